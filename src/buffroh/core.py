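"""Core genotype container shared by every pipeline stage.

Genotype calls are stored as an ``int8`` dosage matrix (individuals x SNPs):
0 = homozygous for allele A, 1 = heterozygous, 2 = homozygous for allele B,
-1 = missing.  The SNP map and the sample sheet travel with the matrix as
pandas DataFrames so that every downstream table can be joined on
``snp_id`` / ``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
HET: int = 1

#: columns required in the SNP map frame
MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
#: columns required in the sample frame
SAMPLE_COLUMNS = ["sample_id", "buffalo_type", "population"]

VALID_TYPES = ("river", "swamp")

#: autosomes analyzed throughout (sex chromosomes / scaffolds are dropped on read)
AUTOSOMES = tuple(range(1, 25))


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype input."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with sample metadata and a genomic map.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per individual with columns ``sample_id``, ``buffalo_type``
        (``river`` or ``swamp``) and ``population``.
    snps : pandas.DataFrame
        One row per marker, sorted by (chromosome, position_bp), with columns
        ``snp_id``, ``chromosome`` (1..24), ``position_bp`` (1-based),
        ``allele_a`` and ``allele_b``.
    calls : numpy.ndarray
        ``int8`` array of shape (n_samples, n_snps) holding allele-B dosages
        with -1 for missing.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise GenotypeError("calls contain codes outside {-1, 0, 1, 2}")
        unknown = set(self.samples["buffalo_type"]) - set(VALID_TYPES)
        if unknown:
            raise GenotypeError(f"unknown buffalo type(s): {sorted(unknown)}")

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given boolean/index selections."""
        sm = np.arange(self.n_samples) if sample_mask is None else np.asarray(sample_mask)
        km = np.arange(self.n_snps) if snp_mask is None else np.asarray(snp_mask)
        if sm.dtype == bool:
            sm = np.flatnonzero(sm)
        if km.dtype == bool:
            km = np.flatnonzero(km)
        return GenotypeMatrix(
            samples=self.samples.iloc[sm].reset_index(drop=True),
            snps=self.snps.iloc[km].reset_index(drop=True),
            calls=self.calls[np.ix_(sm, km)].copy(),
        )

    def type_mask(self, buffalo_type: str) -> np.ndarray:
        if buffalo_type not in VALID_TYPES:
            raise GenotypeError(f"unknown buffalo type {buffalo_type!r}")
        return (self.samples["buffalo_type"] == buffalo_type).to_numpy()

    # ------------------------------------------------------------- statistics
    def call_rate_samples(self) -> np.ndarray:
        """Fraction of non-missing calls per individual."""
        return (self.calls != MISSING).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.calls != MISSING).mean(axis=0)

    def allele_freq(self, sample_mask=None) -> np.ndarray:
        """Allele-B frequency per SNP from non-missing calls (NaN if none)."""
        calls = self.calls if sample_mask is None else self.calls[np.asarray(sample_mask)]
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        dose = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, dose / n_alleles, np.nan)

    def maf(self, sample_mask=None) -> np.ndarray:
        p = self.allele_freq(sample_mask)
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self, sample_mask=None) -> np.ndarray:
        """Per-SNP (n_AA, n_Aa, n_aa) counts over non-missing calls."""
        calls = self.calls if sample_mask is None else self.calls[np.asarray(sample_mask)]
        return np.stack([(calls == g).sum(axis=0) for g in (0, 1, 2)], axis=1)

    def map_span_bp(self) -> int:
        """Mapped genome length: sum over chromosomes of last - first SNP position."""
        g = self.snps.groupby("chromosome")["position_bp"]
        return int((g.max() - g.min()).sum())
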