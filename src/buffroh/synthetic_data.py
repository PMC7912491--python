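"""Synthetic genotype panels with planted autozygosity and full ground truth.

The generator emulates the statistical structure the pipeline assumes rather
than the biology that produced it:

* diploid biallelic genotypes on 24 autosomes at ~1 SNP / 50 kb;
* two diverged buffalo types, each split into breeds/populations that drift
  around the type frequency (Balding–Nichols beta draws);
* array ascertainment bias as a configurable fraction of SNPs forced
  monomorphic in the swamp type;
* autozygosity as explicitly planted homozygous segments per animal
  (Poisson count, mixture-of-exponentials lengths), optionally boosted at
  shared island loci — giving exact truth boundaries for recovery tests.

Default sample composition is the study roster: 185 river animals in 15
breeds and 153 swamp animals in 13 populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GenotypeError, GenotypeMatrix
from .roh_detect import RohParams

__all__ = [
    "PopulationSpec",
    "IslandSpec",
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "truth_recovery_report",
    "STUDY_POPULATIONS",
    "STUDY_ISLANDS",
]


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    buffalo_type: str
    n_animals: int
    f_drift: float = 0.05


@dataclass(frozen=True)
class IslandSpec:
    """A locus where segment planting is boosted, creating a shared island."""

    chromosome: int
    position_bp: int
    boost_river: float = 0.10
    boost_swamp: float = 0.20


# study sample composition: (symbol, type, n)
_STUDY_ROSTER = [
    ("RIVBR_MUR", "river", 30), ("RIVCO", "river", 12), ("RIVEG", "river", 15),
    ("RIVIR_AZA", "river", 9), ("RIVIR_KHU", "river", 10), ("RIVIR_MAZ", "river", 8),
    ("RIVIT_MED", "river", 30), ("RIVMZ", "river", 7), ("RIVPH_BU", "river", 8),
    ("RIVPH_IN", "river", 4), ("RIVPK_AZK", "river", 3), ("RIVPK_KUN", "river", 10),
    ("RIVPK_NIL", "river", 15), ("RIVRO", "river", 9), ("RIVTR_ANA", "river", 15),
    ("SWACN_ENS", "swamp", 15), ("SWACN_FUL", "swamp", 15), ("SWACN_GUI", "swamp", 11),
    ("SWACN_HUN", "swamp", 14), ("SWACN_YAN", "swamp", 12), ("SWACN_YIB", "swamp", 15),
    ("SWAIN_JAV", "swamp", 12), ("SWAIN_NUT", "swamp", 7), ("SWAIN_SUM", "swamp", 8),
    ("SWAIN_SUW", "swamp", 10), ("SWAPH", "swamp", 21), ("SWATH_THS", "swamp", 5),
    ("SWATH_THT", "swamp", 8),
]
STUDY_POPULATIONS = tuple(PopulationSpec(n, t, c) for n, t, c in _STUDY_ROSTER)

#: shared homozygosity hotspots, swamp-skewed as in the study's island tables
STUDY_ISLANDS = (
    IslandSpec(1, 12_000_000, 0.12, 0.22),
    IslandSpec(1, 80_000_000, 0.10, 0.18),
    IslandSpec(2, 50_000_000, 0.20, 0.35),
    IslandSpec(2, 62_000_000, 0.12, 0.22),
    IslandSpec(4, 70_000_000, 0.10, 0.18),
    IslandSpec(13, 51_000_000, 0.08, 0.20),
    IslandSpec(20, 52_000_000, 0.08, 0.18),
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the study conditions."""

    seed: int
    n_chromosomes: int = 24
    chromosome_length_bp: int = 100_000_000
    snps_per_chromosome: int = 2_000
    populations: tuple[PopulationSpec, ...] = STUDY_POPULATIONS
    #: Balding–Nichols divergence of each type from the ancestral (array
    #: discovery) pool.  The array was ascertained on river-like variation,
    #: so river sits close to the ancestral frequencies; swamp drifts
    #: moderately at the SNPs that remain polymorphic in it, while the bulk
    #: of its divergence shows up as fixed loci (the forced fraction below).
    type_divergence: tuple[tuple[str, float], ...] = (("river", 0.05), ("swamp", 0.25))
    #: fraction of SNPs forced monomorphic in swamp, emulating the river-
    #: ascertained array detecting only about one-third of its SNPs in swamp
    swamp_monomorphic_fraction: float = 0.60
    ancestral_maf_range: tuple[float, float] = (0.05, 0.50)
    roh_rate: tuple[tuple[str, float], ...] = (("river", 40.0), ("swamp", 70.0))
    #: length model: min + Exp(short mean) w.p. short_weight, else min + Exp(long mean)
    roh_length_min_bp: int = 1_000_000
    roh_length_short_mean_bp: float = 1_200_000
    roh_length_long_mean_bp: float = 5_000_000
    roh_length_short_weight: float = 0.75
    islands: tuple[IslandSpec, ...] = STUDY_ISLANDS
    island_length_min_bp: int = 1_200_000
    island_length_mean_bp: float = 2_500_000
    missing_rate: float = 0.002
    crisp_boundaries: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.swamp_monomorphic_fraction <= 1:
            raise ValueError("swamp_monomorphic_fraction outside [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate outside [0, 1]")
        if self.chromosome_length_bp <= 0 or self.snps_per_chromosome <= 0:
            raise ValueError("chromosome dimensions must be positive")
        for isl in self.islands:
            if not 1 <= isl.chromosome <= self.n_chromosomes:
                raise GenotypeError(f"island chromosome {isl.chromosome} outside panel")
            if not 0 < isl.position_bp < self.chromosome_length_bp:
                raise GenotypeError(
                    f"island locus {isl.position_bp} outside chromosome span"
                )

    @property
    def roh_rate_by_type(self) -> dict[str, float]:
        return dict(self.roh_rate)

    @property
    def type_divergence_by_type(self) -> dict[str, float]:
        if isinstance(self.type_divergence, (int, float)):
            return {"river": float(self.type_divergence), "swamp": float(self.type_divergence)}
        return dict(self.type_divergence)


@dataclass
class SimTruth:
    """Ground truth of a simulated panel."""

    segments: pd.DataFrame
    ancestral_freq: np.ndarray
    type_freq: dict[str, np.ndarray]
    population_freq: dict[str, np.ndarray] = field(repr=False)
    island_loci: tuple[IslandSpec, ...] = ()
    swamp_monomorphic_mask: np.ndarray | None = None


def _bn_draw(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols beta draw around p with drift parameter f."""
    if f <= 0:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    out = np.where((p > 0) & (p < 1), rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)), p)
    return out


def _draw_positions(rng, config: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom in range(1, config.n_chromosomes + 1):
        pos = np.array([], dtype=np.int64)
        while len(pos) < config.snps_per_chromosome:
            extra = rng.integers(
                1, config.chromosome_length_bp, size=config.snps_per_chromosome * 2
            )
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=config.snps_per_chromosome, replace=False))
        for i, p in enumerate(pos):
            rows.append((f"snp_{chrom}_{i:05d}", chrom, int(p), "A", "C"))
    return pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
    )


def _segment_lengths(rng, config: SimConfig, n: int) -> np.ndarray:
    short = rng.random(n) < config.roh_length_short_weight
    mean = np.where(short, config.roh_length_short_mean_bp, config.roh_length_long_mean_bp)
    return (config.roh_length_min_bp + rng.exponential(mean)).astype(np.int64)


def _plan_segments(rng, config: SimConfig, buffalo_type: str):
    """Plan non-overlapping (chromosome, start, end, island) intervals for one animal."""
    planned: list[tuple[int, int, int, bool]] = []

    def overlaps(chrom, start, end):
        return any(c == chrom and start <= e and end >= s for c, s, e, _ in planned)

    boost_attr = "boost_swamp" if buffalo_type == "swamp" else "boost_river"
    for isl in config.islands:
        if rng.random() >= getattr(isl, boost_attr):
            continue
        length = int(config.island_length_min_bp + rng.exponential(config.island_length_mean_bp))
        offset = rng.integers(0, max(length, 1))
        start = int(np.clip(isl.position_bp - offset, 1, config.chromosome_length_bp - 1))
        end = int(min(start + length, config.chromosome_length_bp))
        if not overlaps(isl.chromosome, start, end):
            planned.append((isl.chromosome, start, end, True))

    n_random = rng.poisson(config.roh_rate_by_type[buffalo_type])
    lengths = _segment_lengths(rng, config, n_random)
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n_random)
    for chrom, length in zip(chroms, lengths):
        length = int(min(length, config.chromosome_length_bp - 2))
        start = int(rng.integers(1, config.chromosome_length_bp - length))
        end = start + length
        if not overlaps(chrom, start, end):
            planned.append((int(chrom), start, end, False))
    return planned


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a genotype panel and its ground truth.

    Deterministic given ``config`` (the seed is part of the config): two runs
    produce byte-identical panels.
    """
    rng = np.random.default_rng(config.seed)
    snps = _draw_positions(rng, config)
    m = len(snps)
    chrom_arr = snps["chromosome"].to_numpy()
    pos_arr = snps["position_bp"].to_numpy()

    lo_maf, hi_maf = config.ancestral_maf_range
    ancestral = rng.uniform(lo_maf, hi_maf, size=m)
    divergence = config.type_divergence_by_type
    type_freq = {
        t: _bn_draw(rng, ancestral, divergence[t]) for t in ("river", "swamp")
    }
    mono_mask = rng.random(m) < config.swamp_monomorphic_fraction
    type_freq["swamp"] = np.where(mono_mask, 0.0, type_freq["swamp"])

    sample_rows = []
    call_blocks = []
    pop_freqs: dict[str, np.ndarray] = {}
    truth_rows = []
    for pop in config.populations:
        pf = _bn_draw(rng, type_freq[pop.buffalo_type], pop.f_drift)
        pop_freqs[pop.name] = pf
        calls = rng.binomial(2, pf, size=(pop.n_animals, m)).astype(np.int8)
        for a in range(pop.n_animals):
            sid = f"{pop.name}_{a + 1:03d}"
            sample_rows.append((sid, pop.buffalo_type, pop.name))
            planned = _plan_segments(rng, config, pop.buffalo_type)
            spanned_idx = []
            for chrom, start, end, is_island in planned:
                inside = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
                idx = np.flatnonzero(inside)
                spanned_idx.append(idx)
                if idx.size:
                    hom_allele = (rng.random(idx.size) < pf[idx]).astype(np.int8) * 2
                    calls[a, idx] = hom_allele
            if config.crisp_boundaries:
                planted = (
                    np.concatenate(spanned_idx) if spanned_idx else np.array([], dtype=int)
                )
                planted_set = set(planted.tolist())
                for (chrom, _s, _e, _i), idx in zip(planned, spanned_idx):
                    if not idx.size:
                        continue
                    for flank in (idx[0] - 1, idx[-1] + 1):
                        if (
                            0 <= flank < m
                            and chrom_arr[flank] == chrom
                            and flank not in planted_set
                            and 0 < pf[flank] < 1
                        ):
                            calls[a, flank] = 1
            for (chrom, start, end, is_island), idx in zip(planned, spanned_idx):
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "buffalo_type": pop.buffalo_type,
                        "population": pop.name,
                        "chromosome": chrom,
                        "start_bp": start,
                        "end_bp": end,
                        "first_snp_bp": int(pos_arr[idx[0]]) if idx.size else -1,
                        "last_snp_bp": int(pos_arr[idx[-1]]) if idx.size else -1,
                        "n_snps_spanned": int(idx.size),
                        "island": is_island,
                    }
                )
        if config.missing_rate > 0:
            miss = rng.random(calls.shape) < config.missing_rate
            calls[miss] = -1
        call_blocks.append(calls)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "buffalo_type", "population"])
    gm = GenotypeMatrix(samples=samples, snps=snps, calls=np.vstack(call_blocks))
    truth = SimTruth(
        segments=pd.DataFrame(
            truth_rows,
            columns=[
                "sample_id", "buffalo_type", "population", "chromosome",
                "start_bp", "end_bp", "first_snp_bp", "last_snp_bp",
                "n_snps_spanned", "island",
            ],
        ),
        ancestral_freq=ancestral,
        type_freq=type_freq,
        population_freq=pop_freqs,
        island_loci=config.islands,
        swamp_monomorphic_mask=mono_mask,
    )
    return gm, truth


def truth_recovery_report(
    detected: pd.DataFrame,
    truth: SimTruth,
    snp_map: pd.DataFrame,
    params: RohParams | None = None,
    tolerance_bp: int | None = None,
    gm: GenotypeMatrix | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Score detected ROH against planted truth.

    A planted segment is *expected recoverable* when the SNPs it spans meet
    the detection criteria (count, spanned length, internal gaps; and, when
    the panel ``gm`` is supplied, the realized calls — e.g. a random missing
    call inside the segment disqualifies it under the no-missing rule).  It counts
    as recovered when detected segments of the same animal overlap it and the
    detected boundaries match the first/last spanned SNP within the tolerance
    (default: the adjacent inter-SNP interval on each side).  Detected
    segments overlapping no planted segment of their animal are false
    discoveries.
    """
    params = params or RohParams()
    chroms = snp_map["chromosome"].to_numpy()
    positions = snp_map["position_bp"].to_numpy()
    sample_row = None
    if gm is not None:
        sample_row = {sid: i for i, sid in enumerate(gm.samples["sample_id"])}

    det_by_sample: dict[tuple, list[tuple[int, int]]] = {}
    for row in detected.itertuples(index=False):
        det_by_sample.setdefault((row.sample_id, row.chromosome), []).append(
            (row.start_bp, row.end_bp)
        )
    matched = {k: np.zeros(len(v), dtype=bool) for k, v in det_by_sample.items()}

    rows = []
    for seg in truth.segments.itertuples(index=False):
        sel = np.flatnonzero(
            (chroms == seg.chromosome)
            & (positions >= seg.start_bp)
            & (positions <= seg.end_bp)
        )
        if sel.size == 0:
            expected = False
            first = last = -1
        else:
            first, last = int(positions[sel[0]]), int(positions[sel[-1]])
            gaps_ok = (
                sel.size < 2
                or int(np.diff(positions[sel]).max()) <= params.max_gap_bp
            )
            expected = (
                sel.size >= params.min_snps
                and (last - first) >= params.min_length_bp
                and gaps_ok
            )
            if expected and sample_row is not None:
                calls = gm.calls[sample_row[seg.sample_id], sel]
                n_het = int((calls == 1).sum())
                n_miss = int((calls == -1).sum())
                expected = n_het <= params.max_het and n_miss <= params.max_missing
        key = (seg.sample_id, seg.chromosome)
        overlapping = []
        for i, (s, e) in enumerate(det_by_sample.get(key, [])):
            if sel.size and s <= last and e >= first:
                overlapping.append((i, s, e))
        for i, _, _ in overlapping:
            matched[key][i] = True
        recovered = False
        start_err = end_err = np.nan
        if overlapping:
            s_min = min(s for _, s, _ in overlapping)
            e_max = max(e for _, _, e in overlapping)
            start_err = abs(s_min - first)
            end_err = abs(e_max - last)
            if tolerance_bp is not None:
                tol_l = tol_r = tolerance_bp
            else:
                tol_l = first - positions[sel[0] - 1] if sel[0] > 0 and chroms[sel[0] - 1] == seg.chromosome else np.inf
                tol_r = positions[sel[-1] + 1] - last if sel[-1] + 1 < len(positions) and chroms[sel[-1] + 1] == seg.chromosome else np.inf
            recovered = start_err <= tol_l and end_err <= tol_r
        rows.append(
            {
                "sample_id": seg.sample_id,
                "chromosome": seg.chromosome,
                "start_bp": seg.start_bp,
                "end_bp": seg.end_bp,
                "n_snps_spanned": seg.n_snps_spanned,
                "expected_recoverable": expected,
                "recovered": recovered,
                "start_error_bp": start_err,
                "end_error_bp": end_err,
            }
        )
    table = pd.DataFrame(rows)
    n_expected = int(table["expected_recoverable"].sum())
    n_recovered = int((table["expected_recoverable"] & table["recovered"]).sum())
    n_false = int(sum((~m).sum() for m in matched.values()))
    metrics = {
        "n_planted": len(table),
        "n_expected_recoverable": n_expected,
        "n_recovered": n_recovered,
        "sensitivity": n_recovered / n_expected if n_expected else np.nan,
        "n_detected": int(len(detected)),
        "n_false_discoveries": n_false,
    }
    return metrics, table
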