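#!/usr/bin/env python
"""Detect runs of homozygosity in each dataset.

Criteria: >= 15 consecutive homozygous called SNPs, >= 1 Mb span, no
inter-SNP gap above 1 Mb, no heterozygous or missing call.  One TSV of
segments per dataset goes under ``results/``.
"""

import sys
from pathlib import Path

from buffroh import detect_roh_all, read_plink_text

SCRATCH = Path("scratch/study")
RESULTS = Path("results")
DATASETS = ["all_data", "river_data", "swamp_data"]


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    for name in DATASETS:
        ds = read_plink_text(
            SCRATCH / f"{name}.ped", SCRATCH / f"{name}.map",
            SCRATCH / f"{name}.samples.tsv",
        )
        rohs = detect_roh_all(ds)
        rohs.to_csv(RESULTS / f"03_{name}_roh.tsv", sep="\t", index=False)
        by_type = rohs.groupby("buffalo_type").size().to_dict()
        print(f"{name.upper()}: {len(rohs)} ROH ({by_type})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
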