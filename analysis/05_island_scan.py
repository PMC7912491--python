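#!/usr/bin/env python
"""Per-SNP ROH incidence, top-1% significant SNPs and ROH islands.

The SNP_ROH track counts, per SNP, the animals carrying it inside a ROH;
SNPs above the 99th percentile are chained into islands (gap <= 1 Mb,
>= 2 SNPs)."""

import sys
from pathlib import Path

import pandas as pd

from buffroh import assemble_islands, read_plink_text, significant_snps, snp_roh_counts

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
        rohs = pd.read_csv(RESULTS / f"03_{name}_roh.tsv", sep="\t")
        track = significant_snps(snp_roh_counts(rohs, ds))
        track.to_csv(RESULTS / f"05_{name}_snp_roh_track.tsv", sep="\t", index=False)
        islands = assemble_islands(track)
        islands.drop(columns=["snp_ids"]).to_csv(
            RESULTS / f"05_{name}_islands.tsv", sep="\t", index=False
        )
        n_sig = int(track["significant"].sum())
        print(
            f"{name.upper()}: {n_sig} significant SNPs on "
            f"{track.loc[track['significant'], 'chromosome'].nunique()} chromosomes, "
            f"{len(islands)} islands"
        )
        if len(islands):
            print(islands.drop(columns=["snp_ids"]).round(2).to_string(index=False))
        print()
    return 0


if __name__ == "__main__":
    sys.exit(main())
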