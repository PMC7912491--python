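#!/usr/bin/env python
"""Summarize ROH: per-animal and per-group counts, lengths, length classes,
unique segments, F_ROH at the 0/2/4/8 Mb thresholds, chromosome
distribution and within-ROH SNP spacing."""

import sys
from pathlib import Path

import pandas as pd

from buffroh import (
    chromosome_distribution,
    classify_lengths,
    count_unique,
    group_summary,
    read_plink_text,
    summarize_animals,
)

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
        total, unique, carriers = count_unique(rohs)
        summary = summarize_animals(rohs, ds.samples, ds.map_span_bp())
        summary.to_csv(RESULTS / f"04_{name}_animal_summary.tsv", sep="\t", index=False)
        group_summary(summary).to_csv(
            RESULTS / f"04_{name}_type_summary.tsv", sep="\t", index=False
        )
        group_summary(summary, by="population").to_csv(
            RESULTS / f"04_{name}_population_summary.tsv", sep="\t", index=False
        )
        classify_lengths(rohs).to_csv(RESULTS / f"04_{name}_length_classes.tsv", sep="\t")
        carriers.head(10).to_csv(
            RESULTS / f"04_{name}_top_shared_roh.tsv", sep="\t", index=False
        )
        per_chrom, spacing = chromosome_distribution(rohs, ds.snps)
        spacing.to_csv(RESULTS / f"04_{name}_roh_snp_spacing.tsv", sep="\t")

        print(f"{name.upper()}: {total} ROH, {unique} unique")
        grp = group_summary(summary)
        cols = ["n_roh_mean", "mean_length_mb_mean", "froh_all_mean", "froh_gt4mb_mean"]
        print(grp.set_index(grp.columns[0])[cols].round(3).to_string())
        print()
    return 0


if __name__ == "__main__":
    sys.exit(main())
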