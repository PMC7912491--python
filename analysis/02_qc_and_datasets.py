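#!/usr/bin/env python
"""Quality control and construction of the three analysis datasets.

Reads the simulated panel from ``scratch/study``, applies the study QC
(sample call rate >= 0.95, SNP call rate >= 0.95, MAF >= 0.01) and builds
ALL_DATA (both types, swamp-polymorphic SNPs), RIVER_DATA and SWAMP_DATA
(one type, re-pruned within type + HWE exact test at P < 1e-5).  Datasets
are re-emitted as PLINK text under ``scratch/study`` for the later stages.
"""

import sys
from pathlib import Path

import pandas as pd

from buffroh import apply_qc, build_datasets, read_plink_text, write_plink_text

SCRATCH = Path("scratch/study")
RESULTS = Path("results")


def main() -> int:
    gm = read_plink_text(
        SCRATCH / "panel.ped", SCRATCH / "panel.map", SCRATCH / "panel.samples.tsv"
    )
    gm_qc, report = apply_qc(gm)
    datasets = build_datasets(gm_qc)

    RESULTS.mkdir(exist_ok=True)
    report.to_frame().to_csv(RESULTS / "02_qc_report.tsv", sep="\t", index=False)

    rows = []
    for name, ds in datasets.items():
        write_plink_text(ds, SCRATCH / name.lower())
        rows.append((name, ds.n_samples, ds.n_snps))
    counts = pd.DataFrame(rows, columns=["dataset", "n_samples", "n_snps"])
    counts.to_csv(RESULTS / "02_dataset_counts.tsv", sep="\t", index=False)
    print(report.to_frame().to_string(index=False))
    print()
    print(counts.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
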