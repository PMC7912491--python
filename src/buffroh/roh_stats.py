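"""Per-animal, per-group and per-chromosome ROH summaries and F_ROH.

F_ROH is the genomic inbreeding coefficient: the fraction of the (mapped)
genome covered by an animal's ROH, optionally restricted to ROH longer than a
threshold (2, 4, 8 Mb in the study's tables).  The default denominator is the
map span — sum over chromosomes of (last - first SNP position) — because it
is reproducible from the input alone; pass ``genome_length_bp`` to override
with an assembly length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = [
    "LENGTH_CLASSES",
    "summarize_animals",
    "group_summary",
    "classify_lengths",
    "count_unique",
    "chromosome_distribution",
]

#: (label, lower_mb, upper_mb]; the first class additionally admits exactly 1 Mb
LENGTH_CLASSES = [
    ("1-2 Mb", 1.0, 2.0),
    ("2-4 Mb", 2.0, 4.0),
    ("4-8 Mb", 4.0, 8.0),
    ("8-16 Mb", 8.0, 16.0),
    (">16 Mb", 16.0, np.inf),
]

DEFAULT_FROH_THRESHOLDS = {
    "froh_all": 0,
    "froh_gt2mb": 2_000_000,
    "froh_gt4mb": 4_000_000,
    "froh_gt8mb": 8_000_000,
}


def summarize_animals(
    rohs: pd.DataFrame,
    samples: pd.DataFrame,
    genome_length_bp: int,
    thresholds: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-animal n_ROH, mean/total length and F_ROH at each length threshold.

    ``samples`` supplies the full roster so that animals without any ROH
    appear with zeros.  F_ROH(t) sums length_bp over ROH with length > t.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    thresholds = DEFAULT_FROH_THRESHOLDS if thresholds is None else thresholds
    if any(t < 0 for t in thresholds.values()):
        raise ValueError("negative F_ROH length threshold")

    base = samples[["sample_id", "buffalo_type", "population"]].copy()
    if rohs.empty:
        agg = pd.DataFrame(
            {"sample_id": [], "n_roh": [], "sum_length_bp": [], "mean_length_mb": []}
        )
    else:
        g = rohs.groupby("sample_id")["length_bp"]
        agg = pd.DataFrame(
            {
                "n_roh": g.size(),
                "sum_length_bp": g.sum(),
                "mean_length_mb": g.mean() / 1e6,
            }
        ).reset_index()
    out = base.merge(agg, on="sample_id", how="left")
    out[["n_roh", "sum_length_bp"]] = out[["n_roh", "sum_length_bp"]].fillna(0).astype(int)
    out["mean_length_mb"] = out["mean_length_mb"].fillna(0.0)

    for name, t in thresholds.items():
        if rohs.empty:
            cov = pd.Series(dtype=float)
        else:
            long = rohs[rohs["length_bp"] > t]
            cov = long.groupby("sample_id")["length_bp"].sum()
        out[name] = (
            out["sample_id"].map(cov).fillna(0.0).to_numpy() / genome_length_bp
        )
    return out


def group_summary(animal_summary: pd.DataFrame, by: str = "buffalo_type") -> pd.DataFrame:
    """Mean +/- SD of the per-animal statistics within each group."""
    value_cols = [c for c in animal_summary.columns if c not in ("sample_id", "buffalo_type", "population")]
    g = animal_summary.groupby(by)[value_cols]
    mean = g.mean().add_suffix("_mean")
    sd = g.std(ddof=1).add_suffix("_sd")
    n = g.size().rename("n_animals")
    return pd.concat([n, mean, sd], axis=1).reset_index()


def _length_class(length_mb: np.ndarray) -> np.ndarray:
    if (length_mb < 1.0).any():
        raise ValueError("ROH shorter than 1 Mb cannot exist after detection")
    labels = np.empty(len(length_mb), dtype=object)
    for label, lo, hi in LENGTH_CLASSES:
        sel = (length_mb > lo) & (length_mb <= hi)
        if lo == 1.0:
            sel |= length_mb == 1.0  # the detection floor belongs to the first class
        labels[sel] = label
    return labels


def classify_lengths(rohs: pd.DataFrame, group_by: str = "buffalo_type") -> pd.DataFrame:
    """Count ROH per length class (boundaries upper-inclusive) per group."""
    class_labels = [c[0] for c in LENGTH_CLASSES]
    if rohs.empty:
        return pd.DataFrame(index=pd.Index(class_labels, name="length_class"))
    df = rohs.copy()
    df["length_class"] = _length_class(df["length_bp"].to_numpy() / 1e6)
    table = (
        df.groupby([group_by, "length_class"], observed=True)
        .size()
        .unstack(group_by, fill_value=0)
        .reindex(class_labels, fill_value=0)
    )
    table.index.name = "length_class"
    return table


def count_unique(rohs: pd.DataFrame) -> tuple[int, int, pd.DataFrame]:
    """Total vs unique ROH signatures plus the carrier table.

    A unique ROH is a distinct (chromosome, start_bp, end_bp) triple.  The
    carrier table lists, per triple, the number of carriers and their
    sample/population lists, sorted by descending carrier count (the "most
    frequently detected ROH" view).
    """
    if rohs.empty:
        return 0, 0, pd.DataFrame(
            columns=["chromosome", "start_bp", "end_bp", "n_carriers", "samples", "populations"]
        )
    g = rohs.groupby(["chromosome", "start_bp", "end_bp"])
    carriers = g.agg(
        n_carriers=("sample_id", "size"),
        samples=("sample_id", lambda s: ",".join(s)),
        populations=("population", lambda s: ",".join(sorted(set(s)))),
    ).reset_index()
    carriers = carriers.sort_values(
        ["n_carriers", "chromosome", "start_bp"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return len(rohs), len(carriers), carriers


def chromosome_distribution(
    rohs: pd.DataFrame, snp_map: pd.DataFrame, group_by: str = "buffalo_type"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome ROH counts/mean lengths and within-ROH SNP spacing.

    Returns ``(per_chromosome, spacing_by_class)`` where the second frame
    gives the mean inter-SNP distance inside ROH (length / (n_snps - 1)) per
    length class and group.
    """
    chroms = pd.Index(sorted(snp_map["chromosome"].unique()), name="chromosome")
    if rohs.empty:
        per_chrom = pd.DataFrame(index=chroms)
        return per_chrom, pd.DataFrame()
    counts = (
        rohs.groupby([group_by, "chromosome"])
        .agg(n_roh=("length_bp", "size"), mean_length_mb=("length_bp", lambda v: v.mean() / 1e6))
        .reset_index()
        .pivot(index="chromosome", columns=group_by)
    )
    per_chrom = counts.reindex(chroms)
    n_cols = [c for c in per_chrom.columns if c[0] == "n_roh"]
    per_chrom[n_cols] = per_chrom[n_cols].fillna(0).astype(int)

    df = rohs.copy()
    df["length_class"] = _length_class(df["length_bp"].to_numpy() / 1e6)
    df["snp_spacing_bp"] = df["length_bp"] / np.maximum(df["n_snps"] - 1, 1)
    spacing = (
        df.groupby([group_by, "length_class"], observed=True)["snp_spacing_bp"]
        .mean()
        .unstack(group_by)
        .reindex([c[0] for c in LENGTH_CLASSES])
    )
    spacing.index.name = "length_class"
    return per_chrom, spacing
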