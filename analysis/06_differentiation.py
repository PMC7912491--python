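#!/usr/bin/env python
"""Between-type differentiation on ALL_DATA: F_ST + LOWESS + 3-SD outliers,
per-SNP logistic regression of ROH membership on type, and the annotated
island table (mean F_ST, odds ratio and per-type SNP_ROH per island)."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from buffroh import (
    assemble_islands,
    call_outliers,
    fst_per_snp,
    island_summary,
    logistic_by_type,
    lowess_smooth,
    read_plink_text,
    roh_membership_matrix,
    significant_snps,
    snp_roh_counts,
)

SCRATCH = Path("scratch/study")
RESULTS = Path("results")


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    ds = read_plink_text(
        SCRATCH / "all_data.ped", SCRATCH / "all_data.map",
        SCRATCH / "all_data.samples.tsv",
    )
    rohs = pd.read_csv(RESULTS / "03_all_data_roh.tsv", sep="\t")

    fst_track = call_outliers(lowess_smooth(fst_per_snp(ds)))
    fst_track.to_csv(RESULTS / "06_all_data_fst.tsv", sep="\t", index=False)
    print(
        f"mean F_ST {np.nanmean(fst_track['fst']):.3f}; "
        f"{int(fst_track['fst_outlier'].sum())} SNPs above mean + 3 SD "
        f"on {fst_track.loc[fst_track['fst_outlier'], 'chromosome'].nunique()} chromosomes"
    )

    member = roh_membership_matrix(rohs, ds)
    logit = logistic_by_type(member, ds.samples, ds.snps)
    logit.to_csv(RESULTS / "06_all_data_logistic.tsv", sep="\t", index=False)
    finite = logit.loc[~logit["separated"], "odds_ratio"]
    print(
        f"logistic scan: {int(logit['significant'].sum())} SNPs at P < 0.01; "
        f"mean OR {finite.mean():.2f} +/- {finite.std(ddof=1):.2f} "
        f"({int(logit['separated'].sum())} separated SNPs excluded)"
    )

    track = significant_snps(snp_roh_counts(rohs, ds))
    islands = assemble_islands(track)
    table = island_summary(islands, track, fst_track, logit)
    table.to_csv(RESULTS / "06_all_data_island_table.tsv", sep="\t", index=False)
    print()
    print(table.round(3).to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
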