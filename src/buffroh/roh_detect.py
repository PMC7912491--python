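"""Rule-based detection of runs of homozygosity (ROH).

A ROH is a maximal stretch of consecutive map SNPs for one animal that is
entirely homozygous and called, with no inter-SNP gap above ``max_gap_bp``,
and that carries at least ``min_snps`` markers over at least
``min_length_bp``.  No sliding window is involved: candidate runs are exact
maximal stretches, then filtered by the two minimum-size criteria.

Defaults are the study settings for a medium-density panel: 15 SNPs, 1 Mb
minimum length, 1 Mb maximum gap, no heterozygous or missing calls allowed.
``max_het`` / ``max_missing`` are exposed for the more permissive settings
used elsewhere in the buffalo literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, GenotypeError, GenotypeMatrix

__all__ = ["RohParams", "detect_roh_sample", "detect_roh_all", "ROH_COLUMNS"]

ROH_COLUMNS = [
    "sample_id",
    "buffalo_type",
    "population",
    "chromosome",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_bp",
]


@dataclass(frozen=True)
class RohParams:
    min_snps: int = 15
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    max_het: int = 0
    max_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("min_snps", "min_length_bp", "max_gap_bp", "max_het", "max_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _runs_strict(calls: np.ndarray, pos: np.ndarray, params: RohParams):
    """Maximal homozygous runs when no het/missing call is tolerated."""
    hom = (calls == 0) | (calls == 2)
    if not hom.any():
        return []
    # a new run starts at 0, after a disqualified SNP, or across a large gap
    new_run = np.empty(len(pos), dtype=bool)
    new_run[0] = True
    new_run[1:] = (~hom[:-1]) | (np.diff(pos) > params.max_gap_bp)
    run_id = np.cumsum(new_run)
    idx = np.flatnonzero(hom)
    rid = run_id[idx]
    first = np.flatnonzero(np.r_[True, rid[1:] != rid[:-1]])
    counts = np.diff(np.r_[first, len(rid)])
    starts = idx[first]
    ends = idx[first + counts - 1]
    return list(zip(starts, ends, counts))


def _window_valid_prefix(calls: np.ndarray, pos: np.ndarray, params: RohParams):
    het = calls == HET
    miss = calls == MISSING
    gap_break = np.r_[False, np.diff(pos) > params.max_gap_bp]
    chet = np.r_[0, np.cumsum(het)]
    cmiss = np.r_[0, np.cumsum(miss)]
    cgap = np.r_[0, np.cumsum(gap_break)]
    return het, miss, chet, cmiss, cgap


def _runs_tolerant(calls: np.ndarray, pos: np.ndarray, params: RohParams):
    """Two-pointer enumeration of maximal windows under het/missing budgets.

    A window is internally valid if it holds at most ``max_het`` heterozygous
    and ``max_missing`` missing calls and no internal gap above the budget;
    emitted runs are trimmed to start/end on homozygous called SNPs.
    """
    n = len(pos)
    het, miss, chet, cmiss, cgap = _window_valid_prefix(calls, pos, params)
    hom = ~(het | miss)

    def valid(i: int, j: int) -> bool:
        return (
            chet[j + 1] - chet[i] <= params.max_het
            and cmiss[j + 1] - cmiss[i] <= params.max_missing
            and cgap[j + 1] - cgap[i + 1] == 0
        )

    out = []
    j = -1
    prev_reach = -1
    for i in range(n):
        if j < i:
            j = i
        if not valid(i, j):
            continue
        while j + 1 < n and valid(i, j + 1):
            j += 1
        if j > prev_reach:  # not extendable left (reach strictly grew)
            prev_reach = j
            # trim to homozygous endpoints
            lo, hi = i, j
            while lo <= hi and not hom[lo]:
                lo += 1
            while hi >= lo and not hom[hi]:
                hi -= 1
            if lo <= hi:
                out.append((lo, hi, int(hi - lo + 1)))
    # trimming can create duplicates / nested windows; keep maximal distinct
    dedup = []
    for seg in out:
        if dedup and seg[0] >= dedup[-1][0] and seg[1] <= dedup[-1][1]:
            continue
        dedup.append(seg)
    return dedup


def detect_roh_sample(
    calls_row: np.ndarray, snp_map: pd.DataFrame, params: RohParams | None = None
) -> pd.DataFrame:
    """Detect ROH on one animal's genotype row.

    ``snp_map`` must be sorted by (chromosome, position_bp) and aligned with
    ``calls_row``.  Returns a frame with chromosome, start_bp, end_bp, n_snps
    and length_bp (= end - start) per run.
    """
    params = params or RohParams()
    calls_row = np.asarray(calls_row)
    if calls_row.shape != (len(snp_map),):
        raise GenotypeError(
            f"calls row length {calls_row.shape} does not match map ({len(snp_map)})"
        )
    chroms = snp_map["chromosome"].to_numpy()
    positions = snp_map["position_bp"].to_numpy()

    records = []
    strict = params.max_het == 0 and params.max_missing == 0
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        pos = positions[sel]
        calls = calls_row[sel]
        runs = (_runs_strict if strict else _runs_tolerant)(calls, pos, params)
        for lo, hi, n in runs:
            length = int(pos[hi] - pos[lo])
            if n >= params.min_snps and length >= params.min_length_bp:
                records.append((int(chrom), int(pos[lo]), int(pos[hi]), int(n), length))
    return pd.DataFrame(
        records, columns=["chromosome", "start_bp", "end_bp", "n_snps", "length_bp"]
    )


def detect_roh_all(gm: GenotypeMatrix, params: RohParams | None = None) -> pd.DataFrame:
    """Detect ROH for every animal; rows ordered by (sample, chromosome, start)."""
    params = params or RohParams()
    frames = []
    for i, srow in enumerate(gm.samples.itertuples(index=False)):
        segs = detect_roh_sample(gm.calls[i], gm.snps, params)
        if segs.empty:
            continue
        segs.insert(0, "population", srow.population)
        segs.insert(0, "buffalo_type", srow.buffalo_type)
        segs.insert(0, "sample_id", srow.sample_id)
        frames.append(segs)
    if not frames:
        return pd.DataFrame(columns=ROH_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["sample_id", "chromosome", "start_bp"], kind="stable"
    ).reset_index(drop=True)
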