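"""Between-type differentiation scans: per-SNP F_ST and logistic ROH odds.

F_ST uses the two-population Wright/Nei form on unweighted group
frequencies:

    H_S = (2 p1 q1 + 2 p2 q2) / 2,   H_T = 2 p_bar q_bar,
    F_ST = (H_T - H_S) / H_T          (0 when H_T = 0),

with a Weir–Cockerham estimator available as an alternative.  The raw track
is denoised per chromosome with LOWESS (tricube-weighted local linear
regression with bisquare robustifying passes) and outliers are SNPs whose
smoothed value lies strictly above mean + 3 SD.

The logistic scan regresses each SNP's per-animal in-ROH indicator on
buffalo type, log(p/(1-p)) = b0 + b_type (river is the reference level), by
Newton/IRLS on the aggregated 2x2 binomial table; the odds ratio
exp(b_type) then equals the table's cross-product ratio at the MLE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import GenotypeError, GenotypeMatrix

__all__ = [
    "fst_per_snp",
    "lowess_smooth",
    "call_outliers",
    "logistic_by_type",
]


# --------------------------------------------------------------------- F_ST
def fst_per_snp(
    gm: GenotypeMatrix, group_col: str = "buffalo_type", estimator: str = "nei"
) -> pd.DataFrame:
    """Per-SNP fixation index between exactly two groups.

    Returns a frame with group allele frequencies and ``fst``; SNPs with no
    called genotype in a group get NaN.  ``estimator`` is ``"nei"`` (default,
    unweighted group frequencies) or ``"weir_cockerham"``.
    """
    groups = list(pd.unique(gm.samples[group_col]))
    if len(groups) != 2:
        raise GenotypeError(f"need exactly 2 groups, found {len(groups)}: {groups}")
    g1, g2 = sorted(groups)
    m1 = (gm.samples[group_col] == g1).to_numpy()
    m2 = (gm.samples[group_col] == g2).to_numpy()
    p1 = gm.allele_freq(sample_mask=m1)
    p2 = gm.allele_freq(sample_mask=m2)

    track = gm.snps[["snp_id", "chromosome", "position_bp"]].copy()
    track[f"freq_{g1}"] = p1
    track[f"freq_{g2}"] = p2
    if estimator == "nei":
        pbar = (p1 + p2) / 2.0
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(ht > 0, (ht - hs) / ht, 0.0)
        fst = np.where(np.isnan(p1) | np.isnan(p2), np.nan, fst)
    elif estimator == "weir_cockerham":
        fst = _weir_cockerham(gm, m1, m2, p1, p2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    track["fst"] = fst
    return track


def _weir_cockerham(gm, m1, m2, p1, p2):
    """Two-population Weir–Cockerham theta (haploid-frequency form)."""
    n1 = (gm.calls[m1] != -1).sum(axis=0).astype(float)
    n2 = (gm.calls[m2] != -1).sum(axis=0).astype(float)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (2 * nbar - 1))
        b = nbar / (2 * nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        theta = np.where(a + b > 0, a / (a + b), 0.0)
    return np.where(np.isnan(p1) | np.isnan(p2), np.nan, theta)


# ------------------------------------------------------------------- LOWESS
def _lowess_1d(x: np.ndarray, y: np.ndarray, span: float, iterations: int) -> np.ndarray:
    """Tricube local linear regression with bisquare robustifying passes."""
    n = len(x)
    k = max(3, min(n, int(round(span * n))))
    # contiguous nearest-neighbour window per target (x is sorted)
    lo = np.zeros(n, dtype=int)
    left = 0
    for i in range(n):
        right = left + k - 1
        while right + 1 < n and x[right + 1] - x[i] < x[i] - x[left]:
            left += 1
            right += 1
        lo[i] = left
    robust = np.ones(n)
    fitted = y.astype(float).copy()
    for it in range(iterations + 1):
        for i in range(n):
            sl = slice(lo[i], lo[i] + k)
            xs = x[sl].astype(float)
            ys = y[sl].astype(float)
            d = np.abs(xs - x[i])
            dmax = d.max()
            w = np.ones_like(d) if dmax == 0 else np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
            w = w * robust[sl]
            sw = w.sum()
            if sw <= 0:
                fitted[i] = ys.mean()
                continue
            xm = (w * xs).sum() / sw
            ym = (w * ys).sum() / sw
            sxx = (w * (xs - xm) ** 2).sum()
            if sxx <= 1e-12 * max(1.0, xm * xm):
                fitted[i] = ym
            else:
                beta = (w * (xs - xm) * (ys - ym)).sum() / sxx
                fitted[i] = ym + beta * (x[i] - xm)
        if it == iterations:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        robust = np.clip(1 - u**2, 0, None) ** 2
    return fitted


def lowess_smooth(
    track: pd.DataFrame,
    value_col: str = "fst",
    span: float = 0.05,
    iterations: int = 3,
    out_col: str = "fst_smoothed",
) -> pd.DataFrame:
    """Smooth a per-SNP track within each chromosome.

    Chromosomes with fewer than 3 (non-NaN) SNPs pass through unchanged; NaN
    values stay NaN and do not enter neighbouring fits.
    """
    out = track.copy()
    smoothed = np.full(len(track), np.nan)
    for _, idx in track.groupby("chromosome").indices.items():
        idx = np.sort(idx)
        x = track["position_bp"].to_numpy()[idx].astype(float)
        y = track[value_col].to_numpy()[idx].astype(float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            smoothed[idx] = y
            continue
        smoothed[idx[ok]] = _lowess_1d(x[ok], y[ok], span, iterations)
    out[out_col] = smoothed
    return out


def call_outliers(track: pd.DataFrame, value_col: str = "fst_smoothed") -> pd.DataFrame:
    """Flag SNPs strictly above mean + 3 SD of the smoothed track."""
    out = track.copy()
    vals = out[value_col].to_numpy()
    finite = vals[np.isfinite(vals)]
    threshold = float(finite.mean() + 3.0 * finite.std(ddof=1))
    out["fst_threshold"] = threshold
    out["fst_outlier"] = vals > threshold
    return out


# ----------------------------------------------------------------- logistic
def logistic_by_type(
    membership: np.ndarray,
    samples: pd.DataFrame,
    snps: pd.DataFrame,
    alpha: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Per-SNP logistic regression of ROH membership on buffalo type.

    ``membership`` is the boolean (n_animals x n_snps) in-ROH indicator.
    River is the reference level, so ``odds_ratio`` > 1 means the SNP is more
    often inside a ROH in swamp than in river animals.  SNPs with an empty
    cell in the 2x2 (type x membership) table are flagged ``separated`` with
    an infinite/zero/NaN odds ratio and no Wald P-value.
    """
    types = samples["buffalo_type"].to_numpy()
    riv = types == "river"
    swa = types == "swamp"
    if not riv.any() or not swa.any():
        raise GenotypeError("both buffalo types required for the logistic scan")
    member = np.asarray(membership, dtype=bool)

    r1 = member[riv].sum(axis=0).astype(float)  # river in-ROH
    r0 = riv.sum() - r1
    s1 = member[swa].sum(axis=0).astype(float)
    s0 = swa.sum() - s1
    separated = (r1 == 0) | (r0 == 0) | (s1 == 0) | (s0 == 0)

    # Newton/IRLS on two aggregated binomial observations, vectorized per SNP
    nr = float(riv.sum())
    ns = float(swa.sum())
    b0 = np.zeros(len(r1))
    b1 = np.zeros(len(r1))
    ok = ~separated
    dev_old = np.full(len(r1), np.inf)
    for _ in range(max_iter):
        mur = 1.0 / (1.0 + np.exp(-b0))
        mus = 1.0 / (1.0 + np.exp(-(b0 + b1)))
        # gradient of the binomial log-likelihood
        g0 = (r1 - nr * mur) + (s1 - ns * mus)
        g1 = s1 - ns * mus
        wr = nr * mur * (1 - mur)
        ws = ns * mus * (1 - mus)
        # Hessian [[wr+ws, ws], [ws, ws]]; analytic 2x2 inverse
        det = (wr + ws) * ws - ws * ws
        det = np.where(det > 0, det, np.nan)
        d0 = (ws * g0 - ws * g1) / det
        d1 = ((wr + ws) * g1 - ws * g0) / det
        b0 = np.where(ok, b0 + np.nan_to_num(d0), b0)
        b1 = np.where(ok, b1 + np.nan_to_num(d1), b1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mur = 1.0 / (1.0 + np.exp(-b0))
            mus = 1.0 / (1.0 + np.exp(-(b0 + b1)))
            dev = -2.0 * (
                r1 * np.log(mur) + r0 * np.log(1 - mur)
                + s1 * np.log(mus) + s0 * np.log(1 - mus)
            )
        if np.all(~ok | (np.abs(dev_old - dev) < tol)):
            break
        dev_old = dev

    with np.errstate(divide="ignore", invalid="ignore"):
        or_sep = np.where(
            (r1 == 0) & (s1 == 0), np.nan,
            np.where((s0 == 0) | (r1 == 0), np.inf, np.where((s1 == 0) | (r0 == 0), 0.0, np.nan)),
        )
    odds_ratio = np.where(separated, or_sep, np.exp(b1))
    with np.errstate(divide="ignore"):
        se = np.where(separated, np.nan, np.sqrt(1 / r1 + 1 / r0 + 1 / s1 + 1 / s0))
    with np.errstate(invalid="ignore"):
        z = b1 / se
        pval = np.where(separated, np.nan, 2.0 * norm.sf(np.abs(z)))

    out = snps[["snp_id", "chromosome", "position_bp"]].copy()
    out["beta0"] = np.where(separated, np.nan, b0)
    out["beta_type"] = np.where(separated, np.nan, b1)
    out["odds_ratio"] = odds_ratio
    out["p_value"] = pval
    out["separated"] = separated
    out["significant"] = pval < alpha
    return out
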