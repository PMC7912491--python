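"""IBS ROH-coded genomic relationship matrix (G_ROH) and its eigen-analysis.

Genotypes are recoded by homozygosity and ROH membership — 0 = heterozygous,
1 = homozygous outside any qualifying ROH, 2 = homozygous inside a ROH longer
than ``threshold_bp`` (default 4 Mb) — and the recoded matrix is normalized
with VanRaden's first method: column frequencies p_i = mean(code)/2,
Z = code - 2 p_i (missing entries zeroed after centering), and

    G = Z Z' / (2 * sum_i p_i (1 - p_i)),

with degenerate columns (p_i in {0, 1}) excluded from numerator and
denominator.  Eigen-decomposition of G summarizes population structure; the
percent variance of component k is its eigenvalue over the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HET, MISSING, GenotypeError, GenotypeMatrix
from .islands import roh_membership_matrix

__all__ = ["recode", "build_grm", "eigen_scores", "EigenResult"]

CODED_MISSING = -1


def recode(gm: GenotypeMatrix, rohs: pd.DataFrame, threshold_bp: int = 4_000_000) -> np.ndarray:
    """ROH-coded genotype matrix: 0 het, 1 hom, 2 hom inside a long ROH.

    Missing genotypes stay missing (-1).  Code 2 requires the genotype to be
    homozygous in that animal *and* inside one of that animal's ROH with
    length_bp > ``threshold_bp``.  Idempotent and order-independent: coding
    depends only on the set of qualifying intervals.
    """
    long_rohs = rohs[rohs["length_bp"] > threshold_bp] if not rohs.empty else rohs
    inside = roh_membership_matrix(long_rohs, gm)
    hom = (gm.calls == 0) | (gm.calls == 2)
    coded = np.where(hom, np.where(inside, 2, 1), 0).astype(np.int8)
    coded[gm.calls == MISSING] = CODED_MISSING
    return coded


def build_grm(coded: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """VanRaden method-1 relationship matrix from the recoded genotypes.

    Returns ``(G, p, denominator)`` where ``p`` holds the per-column code
    frequencies (NaN for columns excluded as degenerate).
    """
    coded = np.asarray(coded)
    if coded.ndim != 2 or coded.shape[0] < 2:
        raise GenotypeError("need a 2-D coded matrix with at least 2 samples")
    called = coded != CODED_MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(called, coded, 0).sum(axis=0) / (2.0 * n_called), np.nan)
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise GenotypeError("all coded columns are degenerate; GRM denominator is zero")
    Z = np.where(called, coded, 0).astype(float) - 2.0 * np.where(np.isfinite(p), p, 0.0)
    Z[~called] = 0.0
    Z = Z[:, usable]
    denom = 2.0 * float(np.sum(p[usable] * (1.0 - p[usable])))
    G = Z @ Z.T / denom
    p_out = np.where(usable, p, np.nan)
    return G, p_out, denom


@dataclass
class EigenResult:
    """Eigen-decomposition of G with variance shares and population means."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)  # columns, sorted with eigenvalues
    percent_variance: np.ndarray
    population_means: pd.DataFrame
    type_means: pd.DataFrame


def eigen_scores(
    G: np.ndarray, samples: pd.DataFrame, n_components: int | None = None
) -> EigenResult:
    """Full symmetric eigen-decomposition of G, eigenvalues descending.

    Percent variance is eigenvalue / trace x 100 (sums to 100 over all
    components).  Sign convention: each eigenvector's largest-magnitude
    coefficient is made positive.  Per-population and per-type means of the
    leading eigenvector coefficients are returned for structure plots.
    """
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-10):
        raise GenotypeError("G is not symmetric")
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    flip = v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])] < 0
    v[:, flip] *= -1.0
    pct = w / w.sum() * 100.0

    k = n_components or min(10, len(w))
    scores = pd.DataFrame(
        v[:, :k], columns=[f"ev{i + 1}" for i in range(k)]
    )
    scores["population"] = samples["population"].to_numpy()
    scores["buffalo_type"] = samples["buffalo_type"].to_numpy()
    pop_means = scores.groupby("population").mean(numeric_only=True).reset_index()
    type_means = scores.groupby("buffalo_type").mean(numeric_only=True).reset_index()
    return EigenResult(
        eigenvalues=w,
        eigenvectors=v,
        percent_variance=pct,
        population_means=pop_means,
        type_means=type_means,
    )
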