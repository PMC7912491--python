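"""Shared fixtures and independent brute-force oracles.

The oracle implementations deliberately take a different algorithmic route
from the package (window enumeration instead of linear scans, exact integer
combinatorics instead of log-gamma sums, plain loops instead of vectorized
smoothing) so that agreement is informative.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from buffroh import GenotypeMatrix, PopulationSpec, IslandSpec, SimConfig, simulate_panel
from buffroh.roh_detect import RohParams


# ------------------------------------------------------------------ oracles
def oracle_roh_windows(calls: np.ndarray, pos: np.ndarray, params: RohParams) -> list:
    """Enumerate every (i, j) window; keep valid, maximal, size-qualified ones.

    Only supports the strict setting (no het/missing tolerated).  Validity of
    window [i, j]: every call homozygous and called, every internal gap at
    most max_gap_bp.  Maximality: extending one SNP either way breaks
    validity.  Returns (start_idx, end_idx, n_snps) triples.
    """
    assert params.max_het == 0 and params.max_missing == 0
    n = len(pos)
    hom = (calls == 0) | (calls == 2)
    link = hom[:-1] & hom[1:] & (np.diff(pos) <= params.max_gap_bp)
    chom = np.concatenate([[0], np.cumsum(hom)])
    clink = np.concatenate([[0], np.cumsum(link)])
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    all_hom = chom[jj + 1] - chom[ii] == jj - ii + 1
    all_link = clink[jj] - clink[ii] == jj - ii
    valid = (jj >= ii) & all_hom & all_link

    left_ext = np.zeros_like(valid)
    left_ext[1:, :] = valid[:-1, :]
    right_ext = np.zeros_like(valid)
    right_ext[:, :-1] = valid[:, 1:]
    maximal = valid & ~left_ext & ~right_ext

    out = []
    for i, j in zip(*np.nonzero(maximal)):
        n_snps = j - i + 1
        if n_snps >= params.min_snps and pos[j] - pos[i] >= params.min_length_bp:
            out.append((int(i), int(j), int(n_snps)))
    return sorted(out)


def oracle_hwe(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    def weight(het: int) -> Fraction:
        aa = (rare - het) // 2
        AA = n - aa - het
        return Fraction(2**het) * Fraction(
            comb(n, AA) * comb(n - AA, het)
        )

    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


def oracle_lowess(x, y, span: float, iterations: int):
    """Plain-loop tricube local linear regression (mirrors the documented
    convention: k nearest neighbours, bisquare robustifying passes)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    k = max(3, min(n, int(round(span * n))))

    def window(i):
        # contiguous window of k points with the smallest max distance
        best = None
        for lo in range(0, n - k + 1):
            d = max(abs(x[lo] - x[i]), abs(x[lo + k - 1] - x[i]))
            if best is None or d < best[0]:
                best = (d, lo)
        return list(range(best[1], best[1] + k))

    robust = [1.0] * n
    fitted = list(y)
    for it in range(iterations + 1):
        for i in range(n):
            idx = window(i)
            d = [abs(x[j] - x[i]) for j in idx]
            dmax = max(d)
            if dmax == 0:
                w = [1.0] * len(idx)
            else:
                w = [max(0.0, 1 - (dj / dmax) ** 3) ** 3 for dj in d]
            w = [wj * robust[j] for wj, j in zip(w, idx)]
            sw = sum(w)
            if sw <= 0:
                fitted[i] = sum(y[j] for j in idx) / len(idx)
                continue
            xm = sum(wj * x[j] for wj, j in zip(w, idx)) / sw
            ym = sum(wj * y[j] for wj, j in zip(w, idx)) / sw
            sxx = sum(wj * (x[j] - xm) ** 2 for wj, j in zip(w, idx))
            if sxx <= 1e-12 * max(1.0, xm * xm):
                fitted[i] = ym
            else:
                beta = sum(wj * (x[j] - xm) * (y[j] - ym) for wj, j in zip(w, idx)) / sxx
                fitted[i] = ym + beta * (x[i] - xm)
        if it == iterations:
            break
        resid = [yi - fi for yi, fi in zip(y, fitted)]
        s = float(np.median([abs(r) for r in resid]))
        if s <= 0:
            break
        robust = [max(0.0, 1 - (r / (6 * s)) ** 2) ** 2 for r in resid]
    return fitted


# ----------------------------------------------------------------- fixtures
def make_matrix(calls, positions, chromosomes=None, types=None, populations=None):
    """Construct a small GenotypeMatrix from plain lists."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chromosomes = chromosomes or [1] * m
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "allele_a": ["A"] * m,
            "allele_b": ["C"] * m,
        }
    )
    types = types or ["river"] * n
    populations = populations or [f"P{t}" for t in types]
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n)],
            "buffalo_type": types,
            "population": populations,
        }
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


@pytest.fixture(scope="session")
def small_two_type_panel():
    """Moderate two-type panel with planted islands, shared across tests."""
    config = SimConfig(
        seed=20260928,
        n_chromosomes=6,
        snps_per_chromosome=1500,
        populations=(
            PopulationSpec("RIV_A", "river", 15, 0.05),
            PopulationSpec("RIV_B", "river", 15, 0.05),
            PopulationSpec("SWA_A", "swamp", 15, 0.05),
            PopulationSpec("SWA_B", "swamp", 15, 0.05),
        ),
        swamp_monomorphic_fraction=0.4,
        islands=(
            IslandSpec(1, 20_000_000, 0.15, 0.30),
            IslandSpec(2, 50_000_000, 0.20, 0.35),
            IslandSpec(2, 62_000_000, 0.10, 0.25),
            IslandSpec(4, 70_000_000, 0.10, 0.20),
            IslandSpec(5, 30_000_000, 0.10, 0.20),
        ),
        roh_rate=(("river", 15.0), ("swamp", 25.0)),
    )
    return simulate_panel(config)
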