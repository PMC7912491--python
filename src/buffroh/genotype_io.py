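"""PLINK-text input/output, quality control and dataset construction.

The study design builds three datasets from one jointly QC'd panel:

* ``ALL_DATA`` — both buffalo types, restricted to SNPs polymorphic among the
  swamp animals (to temper the river-biased ascertainment of the array);
* ``RIVER_DATA`` / ``SWAMP_DATA`` — one type's animals, re-pruned for call
  rate and MAF within type, with an additional Hardy–Weinberg exact-test
  filter at P < 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AUTOSOMES,
    MAP_COLUMNS,
    MISSING,
    SAMPLE_COLUMNS,
    VALID_TYPES,
    GenotypeError,
    GenotypeMatrix,
)

__all__ = [
    "QCParams",
    "QCReport",
    "read_plink_text",
    "write_plink_text",
    "read_sample_sheet",
    "hwe_exact_p",
    "apply_qc",
    "build_datasets",
]


@dataclass
class QCParams:
    """Quality-control thresholds (defaults are the study's settings)."""

    min_sample_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_p_threshold: float | None = None
    require_polymorphic_in: str | None = None

    def __post_init__(self) -> None:
        for name in ("min_sample_call_rate", "min_snp_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hwe_p_threshold is not None and not 0.0 <= self.hwe_p_threshold <= 1.0:
            raise ValueError("hwe_p_threshold outside [0, 1]")
        if self.require_polymorphic_in is not None and (
            self.require_polymorphic_in not in VALID_TYPES
        ):
            raise ValueError(f"unknown type {self.require_polymorphic_in!r}")


@dataclass
class QCReport:
    """Per-filter removal counts plus retained identifiers."""

    n_samples_in: int
    n_snps_in: int
    n_samples_removed: int
    n_snps_removed_per_filter: dict[str, int]
    retained_sample_ids: list[str]
    retained_snp_ids: list[str]

    @property
    def n_snps_removed(self) -> int:
        return sum(self.n_snps_removed_per_filter.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_call_rate", self.n_samples_removed)]
        rows += list(self.n_snps_removed_per_filter.items())
        rows += [
            ("retained_samples", len(self.retained_sample_ids)),
            ("retained_snps", len(self.retained_snp_ids)),
        ]
        return pd.DataFrame(rows, columns=["filter", "count"])


# --------------------------------------------------------------------------- IO
def read_sample_sheet(path) -> pd.DataFrame:
    """Read the TSV sample sheet (columns sample_id, type, population)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    rename = {"type": "buffalo_type"}
    sheet = sheet.rename(columns=rename)
    missing_cols = set(SAMPLE_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise GenotypeError(f"sample sheet {path} missing columns {sorted(missing_cols)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenotypeError(f"duplicate sample ids in sheet: {dupes[:5]}")
    return sheet[SAMPLE_COLUMNS]


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise GenotypeError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}"
                )
            chrom_s, snp_id, _cm, pos_s = parts
            try:
                chrom = int(chrom_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise GenotypeError(f"{map_path}:{lineno}: non-integer field") from exc
            rows.append((snp_id, chrom, pos))
    snps = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])
    if snps.empty:
        raise GenotypeError(f"{map_path}: empty map")
    return snps


def read_plink_text(ped_path, map_path, sample_sheet_path) -> GenotypeMatrix:
    """Read whitespace-delimited PLINK ``.ped``/``.map`` plus a sample sheet.

    Allele "0" is missing.  SNPs outside chromosomes 1..24 are dropped; the
    map is sorted by (chromosome, position) and call columns permuted with it.
    Per SNP, ``allele_a``/``allele_b`` are the lexicographically sorted
    observed alleles and calls are stored as allele-B dosage.
    """
    snps = _read_map(map_path)
    sheet = read_sample_sheet(sample_sheet_path)
    n_snps = len(snps)

    sample_ids: list[str] = []
    rows_a1 = []
    rows_a2 = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2x{n_snps}), got {len(parts)}"
                )
            sample_ids.append(parts[1])
            alleles = np.array(parts[6:], dtype="U1")
            rows_a1.append(alleles[0::2])
            rows_a2.append(alleles[1::2])
    if not sample_ids:
        raise GenotypeError(f"{ped_path}: no genotype rows")
    unknown = set(sample_ids) - set(sheet["sample_id"])
    if unknown:
        raise GenotypeError(f"samples absent from sheet: {sorted(unknown)[:5]}")

    a1 = np.stack(rows_a1)
    a2 = np.stack(rows_a2)

    calls = np.full(a1.shape, MISSING, dtype=np.int8)
    allele_a = np.empty(n_snps, dtype="U1")
    allele_b = np.empty(n_snps, dtype="U1")
    for j in range(n_snps):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = sorted(set(col[col != "0"]))
        if len(obs) > 2:
            raise GenotypeError(f"SNP {snps['snp_id'][j]}: >2 alleles observed {obs}")
        allele_a[j] = obs[0] if obs else "0"
        allele_b[j] = obs[1] if len(obs) > 1 else "0"
        called = (a1[:, j] != "0") & (a2[:, j] != "0")
        dose = (a1[:, j] == allele_b[j]).astype(np.int8) + (a2[:, j] == allele_b[j])
        calls[called, j] = dose[called]

    snps["allele_a"] = allele_a
    snps["allele_b"] = allele_b

    keep = snps["chromosome"].isin(AUTOSOMES).to_numpy()
    snps = snps[keep].reset_index(drop=True)
    calls = calls[:, keep]
    order = np.lexsort((snps["position_bp"].to_numpy(), snps["chromosome"].to_numpy()))
    snps = snps.iloc[order].reset_index(drop=True)
    calls = calls[:, order]

    samples = (
        pd.DataFrame({"sample_id": sample_ids})
        .merge(sheet, on="sample_id", how="left", validate="one_to_one")
    )
    return GenotypeMatrix(samples=samples, snps=snps[MAP_COLUMNS], calls=calls)


def write_plink_text(gm: GenotypeMatrix, prefix) -> tuple[Path, Path, Path]:
    """Emit ``<prefix>.ped``, ``<prefix>.map`` and ``<prefix>.samples.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    sheet_path = prefix.parent / f"{prefix.name}.samples.tsv"

    with open(map_path, "w") as fh:
        for row in gm.snps.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")

    aa = gm.snps["allele_a"].to_numpy()
    ab = gm.snps["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(gm.samples.itertuples(index=False)):
            dose = gm.calls[i]
            first = np.where(dose >= 1, ab, aa)
            second = np.where(dose == 2, ab, aa)
            miss = dose == MISSING
            first = np.where(miss, "0", first)
            second = np.where(miss, "0", second)
            pairs = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"{srow.population} {srow.sample_id} 0 0 0 -9 {pairs}\n")

    gm.samples.rename(columns={"buffalo_type": "type"}).to_csv(
        sheet_path, sep="\t", index=False
    )
    return ped_path, map_path, sheet_path


# ---------------------------------------------------------------- HWE exact test
@lru_cache(maxsize=100_000)
def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test probability.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the observed
    configuration.  Monomorphic input returns 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype counts")
    n_a = n_Aa + 2 * n_aa  # minor-ish allele count (symmetric in practice)
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    from scipy.special import gammaln

    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het) up to a constant: n! / (nAA! nAa! naa!) * 2^nAa
    n_aa_k = (rare - hets) // 2
    n_AA_k = n - n_aa_k - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(n_AA_k + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_k + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_exact_p_snps(gm: GenotypeMatrix, sample_mask=None) -> np.ndarray:
    """Vectorized wrapper: exact HWE P for every SNP."""
    counts = gm.genotype_counts(sample_mask)
    return np.array([hwe_exact_p(int(a), int(b), int(c)) for a, b, c in counts])


# ------------------------------------------------------------------------- QC
def apply_qc(gm: GenotypeMatrix, params: QCParams | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC cascade: samples by call rate first, then SNP filters.

    SNP filters run in order call rate -> MAF -> (optional) HWE ->
    (optional) polymorphic-within-type; the report itemizes removals per
    filter, attributing each removed SNP to the first filter it fails.
    """
    params = params or QCParams()
    if gm.n_samples == 0 or gm.n_snps == 0:
        raise GenotypeError("empty dataset before QC")

    keep_samples = gm.call_rate_samples() >= params.min_sample_call_rate
    n_samples_removed = int((~keep_samples).sum())
    gm1 = gm.subset(sample_mask=keep_samples)
    if gm1.n_samples == 0:
        raise GenotypeError("empty dataset: all samples removed by call-rate filter")

    removed: dict[str, int] = {}
    keep = np.ones(gm1.n_snps, dtype=bool)

    fail_cr = gm1.call_rate_snps() < params.min_snp_call_rate
    removed["snp_call_rate"] = int((fail_cr & keep).sum())
    keep &= ~fail_cr

    maf = gm1.maf()
    fail_maf = ~(maf >= params.min_maf)  # NaN (all-missing) fails too
    removed["snp_maf"] = int((fail_maf & keep).sum())
    keep &= ~fail_maf

    if params.hwe_p_threshold is not None:
        pvals = np.ones(gm1.n_snps)
        idx = np.flatnonzero(keep)
        counts = gm1.genotype_counts()[idx]
        pvals[idx] = [hwe_exact_p(int(a), int(b), int(c)) for a, b, c in counts]
        fail_hwe = pvals < params.hwe_p_threshold
        removed["snp_hwe"] = int((fail_hwe & keep).sum())
        keep &= ~fail_hwe

    if params.require_polymorphic_in is not None:
        mask = gm1.type_mask(params.require_polymorphic_in)
        if not mask.any():
            raise GenotypeError(
                f"no retained samples of type {params.require_polymorphic_in!r}"
            )
        maf_t = gm1.maf(sample_mask=mask)
        fail_poly = ~(maf_t > 0)
        removed["snp_monomorphic_in_type"] = int((fail_poly & keep).sum())
        keep &= ~fail_poly

    if not keep.any():
        raise GenotypeError("empty dataset: all SNPs removed by QC")
    gm2 = gm1.subset(snp_mask=keep)
    report = QCReport(
        n_samples_in=gm.n_samples,
        n_snps_in=gm.n_snps,
        n_samples_removed=n_samples_removed,
        n_snps_removed_per_filter=removed,
        retained_sample_ids=gm2.samples["sample_id"].tolist(),
        retained_snp_ids=gm2.snps["snp_id"].tolist(),
    )
    return gm2, report


def build_datasets(
    gm: GenotypeMatrix,
    qc_params: QCParams | None = None,
    hwe_p_threshold: float = 1e-5,
) -> dict[str, GenotypeMatrix]:
    """Build ALL_DATA / RIVER_DATA / SWAMP_DATA from a jointly QC'd panel.

    ``gm`` must already have passed the joint sample/SNP call-rate and MAF QC
    (see :func:`apply_qc`).  ALL_DATA keeps both types but only SNPs with both
    alleles observed among the swamp animals; the type-specific datasets keep
    one type's animals and re-apply call-rate/MAF pruning within type plus the
    Hardy–Weinberg exact-test filter.
    """
    qc_params = qc_params or QCParams()
    for t in VALID_TYPES:
        if not gm.type_mask(t).any():
            raise GenotypeError(f"type {t!r} absent from sample sheet")

    swamp_maf = gm.maf(sample_mask=gm.type_mask("swamp"))
    all_data = gm.subset(snp_mask=swamp_maf > 0)

    per_type = {}
    for t in VALID_TYPES:
        sub = gm.subset(sample_mask=gm.type_mask(t))
        params_t = QCParams(
            min_sample_call_rate=qc_params.min_sample_call_rate,
            min_snp_call_rate=qc_params.min_snp_call_rate,
            min_maf=qc_params.min_maf,
            hwe_p_threshold=hwe_p_threshold,
        )
        per_type[t], _ = apply_qc(sub, params_t)
    return {
        "ALL_DATA": all_data,
        "RIVER_DATA": per_type["river"],
        "SWAMP_DATA": per_type["swamp"],
    }
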