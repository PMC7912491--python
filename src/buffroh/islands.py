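"""SNP_ROH incidence track, top-1% significant SNPs and ROH islands.

SNP_ROH is, for each SNP, the number of animals carrying that SNP inside a
detected ROH.  SNPs whose count strictly exceeds the empirical 99th
percentile (nearest rank, zeros included) are significant; chains of >= 2
significant SNPs with consecutive members <= 1 Mb apart form ROH islands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = [
    "roh_membership_matrix",
    "snp_roh_counts",
    "significant_snps",
    "assemble_islands",
    "island_summary",
]


def roh_membership_matrix(rohs: pd.DataFrame, gm: GenotypeMatrix) -> np.ndarray:
    """Boolean (n_samples x n_snps) matrix: SNP inside a ROH of that animal.

    Membership uses inclusive interval endpoints on the map positions.
    """
    n, m = gm.n_samples, gm.n_snps
    member = np.zeros((n, m), dtype=bool)
    if rohs.empty:
        return member
    sample_idx = pd.Series(np.arange(n), index=gm.samples["sample_id"])
    chroms = gm.snps["chromosome"].to_numpy()
    positions = gm.snps["position_bp"].to_numpy()
    # chromosome offsets into the globally sorted map
    chrom_start = {c: np.searchsorted(chroms, c, side="left") for c in np.unique(chroms)}
    chrom_end = {c: np.searchsorted(chroms, c, side="right") for c in np.unique(chroms)}

    diff = np.zeros((n, m + 1), dtype=np.int32)
    rows = rohs["sample_id"].map(sample_idx).to_numpy()
    for row, chrom, start, end in zip(
        rows, rohs["chromosome"].to_numpy(), rohs["start_bp"].to_numpy(), rohs["end_bp"].to_numpy()
    ):
        lo = chrom_start[chrom]
        hi = chrom_end[chrom]
        i0 = lo + np.searchsorted(positions[lo:hi], start, side="left")
        i1 = lo + np.searchsorted(positions[lo:hi], end, side="right")
        diff[row, i0] += 1
        diff[row, i1] -= 1
    member = np.cumsum(diff[:, :-1], axis=1) > 0
    return member


def snp_roh_counts(rohs: pd.DataFrame, gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP SNP_ROH counts and percentages, overall and per type."""
    member = roh_membership_matrix(rohs, gm)
    track = gm.snps[["snp_id", "chromosome", "position_bp"]].copy()
    track["snp_roh"] = member.sum(axis=0)
    track["snp_roh_pct"] = track["snp_roh"] / gm.n_samples * 100.0
    for t in ("river", "swamp"):
        mask = gm.type_mask(t)
        if mask.any():
            track[f"snp_roh_{t}"] = member[mask].sum(axis=0)
            track[f"snp_roh_pct_{t}"] = track[f"snp_roh_{t}"] / mask.sum() * 100.0
    return track


def significant_snps(track: pd.DataFrame, quantile: float = 0.99) -> pd.DataFrame:
    """Flag SNPs whose count strictly exceeds the nearest-rank percentile.

    The percentile is taken over all SNP counts, zeros included; with a flat
    track nothing can strictly exceed it, so nothing is flagged.
    """
    if track.empty:
        raise ValueError("empty SNP_ROH track")
    counts = track["snp_roh"].to_numpy()
    rank = int(np.ceil(quantile * len(counts)))
    threshold = np.sort(counts)[rank - 1]
    out = track.copy()
    out["snp_roh_threshold"] = threshold
    out["significant"] = counts > threshold
    return out


def assemble_islands(
    track: pd.DataFrame,
    max_gap_bp: int = 1_000_000,
    min_snps: int = 2,
) -> pd.DataFrame:
    """Chain significant SNPs into ROH islands.

    Consecutive significant SNPs on one chromosome are chained while they are
    at most ``max_gap_bp`` apart; chains with fewer than ``min_snps`` members
    are discarded.  The island spans the first to last member SNP.
    """
    sig = track[track["significant"]]
    records = []
    for chrom, sub in sig.groupby("chromosome"):
        pos = sub["position_bp"].to_numpy()
        ids = sub["snp_id"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp) + 1
        for chunk_idx in np.split(np.arange(len(pos)), breaks):
            if len(chunk_idx) < min_snps:
                continue
            records.append(
                {
                    "chromosome": int(chrom),
                    "start_bp": int(pos[chunk_idx[0]]),
                    "end_bp": int(pos[chunk_idx[-1]]),
                    "n_snps": int(len(chunk_idx)),
                    "length_mb": float((pos[chunk_idx[-1]] - pos[chunk_idx[0]]) / 1e6),
                    "snp_ids": list(ids[chunk_idx]),
                }
            )
    return pd.DataFrame(
        records,
        columns=["chromosome", "start_bp", "end_bp", "n_snps", "length_mb", "snp_ids"],
    )


def island_summary(
    islands: pd.DataFrame,
    track: pd.DataFrame,
    fst_track: pd.DataFrame | None = None,
    logistic_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate islands with mean +/- SD of member-SNP statistics.

    Attaches mean F_ST of member SNPs (with the chromosome-wide mean for
    contrast), mean odds ratio from the per-SNP logistic scan (non-finite
    odds ratios excluded) and per-type SNP_ROH percentages.
    """
    out = islands.drop(columns=["snp_ids"]).copy()
    by_snp = track.set_index("snp_id")
    fst_by_snp = fst_track.set_index("snp_id") if fst_track is not None else None
    or_by_snp = logistic_results.set_index("snp_id") if logistic_results is not None else None

    def _stats(values):
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if len(values) == 0:
            return np.nan, np.nan
        return float(values.mean()), float(values.std(ddof=1)) if len(values) > 1 else 0.0

    rows = []
    for isl in islands.itertuples(index=False):
        member_ids = list(isl.snp_ids)
        missing = [s for s in member_ids if s not in by_snp.index]
        if missing:
            raise KeyError(f"island member SNPs missing from track: {missing[:3]}")
        rec = {}
        for t in ("river", "swamp"):
            col = f"snp_roh_pct_{t}"
            if col in by_snp.columns:
                m, s = _stats(by_snp.loc[member_ids, col])
                rec[f"snp_roh_pct_{t}_mean"] = m
                rec[f"snp_roh_pct_{t}_sd"] = s
        if fst_by_snp is not None:
            missing = [s for s in member_ids if s not in fst_by_snp.index]
            if missing:
                raise KeyError(f"island member SNPs missing from F_ST track: {missing[:3]}")
            m, s = _stats(fst_by_snp.loc[member_ids, "fst"])
            rec["fst_mean"] = m
            rec["fst_sd"] = s
            chrom_vals = fst_by_snp.loc[fst_by_snp["chromosome"] == isl.chromosome, "fst"]
            rec["fst_chromosome_mean"] = float(np.nanmean(chrom_vals)) if len(chrom_vals) else np.nan
        if or_by_snp is not None:
            missing = [s for s in member_ids if s not in or_by_snp.index]
            if missing:
                raise KeyError(f"island member SNPs missing from logistic track: {missing[:3]}")
            m, s = _stats(or_by_snp.loc[member_ids, "odds_ratio"])
            rec["odds_ratio_mean"] = m
            rec["odds_ratio_sd"] = s
        rows.append(rec)
    return pd.concat([out, pd.DataFrame(rows, index=out.index)], axis=1)
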