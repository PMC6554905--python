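"""Pseudostem-versus-blade tissue analyses.

Ryegrass partitions nitrogen and sugars very differently between the upper
leaf blades (BL) and the lower sheath-like pseudostems (PS): blades run
~1.1 percentage points higher in nitrogen while pseudostems store far more
water-soluble carbohydrate.  This module provides the paired statistics for
those contrasts, the BL-on-PS regressions, the crude-protein conversion
(N x 6.25), and a canonical variate analysis that separates the two
tissues from their SNV spectra.

Sign convention: all contrasts are stored as BL - PS (blade minus
pseudostem); magnitudes are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .preprocess import subsample_bands

__all__ = [
    "TissueContrast",
    "CanonicalProjection",
    "tissue_contrast",
    "relative_partitioning",
    "crude_protein",
    "ps_bl_regression",
    "tissue_cva",
]


@dataclass
class TissueContrast:
    attribute: str
    mean_ps: float
    mean_bl: float
    sd_ps: float
    sd_bl: float
    diff: float          # mean_bl - mean_ps
    se_diff: float
    p_value: float
    n: int


@dataclass
class CanonicalProjection:
    directions: np.ndarray   # (bands, 2), scaled to unit within-group score variance
    scores: np.ndarray       # (n, 2)
    wilks_lambda: float
    labels: np.ndarray


def tissue_contrast(
    ps: np.ndarray, bl: np.ndarray, attribute: str = ""
) -> TissueContrast:
    """Paired BL - PS contrast with a two-sided paired t-test.

    ``ps[i]`` and ``bl[i]`` must come from the same plant i.  When every
    within-plant difference is identical the t statistic is undefined; the
    p-value is then 1.0 for a zero difference and 0.0 otherwise.
    """
    ps = np.asarray(ps, dtype=float).ravel()
    bl = np.asarray(bl, dtype=float).ravel()
    if len(ps) != len(bl):
        raise ValueError(
            f"unpaired input: {len(ps)} PS values vs {len(bl)} BL values"
        )
    n = len(ps)
    if n < 2:
        raise ValueError("need at least 2 plant pairs")
    diffs = bl - ps
    se = float(diffs.std(ddof=1) / np.sqrt(n))
    if se == 0:
        p = 1.0 if diffs[0] == 0 else 0.0
    else:
        p = float(stats.ttest_rel(bl, ps).pvalue)
    return TissueContrast(
        attribute=attribute,
        mean_ps=float(ps.mean()),
        mean_bl=float(bl.mean()),
        sd_ps=float(ps.std(ddof=1)),
        sd_bl=float(bl.std(ddof=1)),
        diff=float(diffs.mean()),
        se_diff=se,
        p_value=p,
        n=n,
    )


def relative_partitioning(
    lmw_ps: float, lmw_bl: float, hmw_ps: float, hmw_bl: float
) -> float:
    """Blade enrichment of LMW sugars relative to HMW sugars.

    Returns (lmw_bl/lmw_ps) / (hmw_bl/hmw_ps): how many times more
    concentrated in the blades (relative to pseudostems) the low-molecular-
    weight fraction is compared to the high-molecular-weight fraction.
    """
    for name, v in (("lmw_ps", lmw_ps), ("lmw_bl", lmw_bl),
                    ("hmw_ps", hmw_ps), ("hmw_bl", hmw_bl)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (lmw_bl / lmw_ps) / (hmw_bl / hmw_ps)


def crude_protein(total_nitrogen_percent) -> float | np.ndarray:
    """Crude protein (%) from total nitrogen (%): N x 6.25."""
    n = np.asarray(total_nitrogen_percent, dtype=float)
    if np.any(n < 0):
        raise ValueError("nitrogen content cannot be negative")
    out = n * 6.25
    return float(out) if out.ndim == 0 else out


def ps_bl_regression(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS of blade values on pseudostem values (y = a + b x).

    Returns slope, slope_se, intercept, intercept_se, r2 (squared Pearson
    correlation) and RMSE of the fit residuals.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    ols = stats.linregress(x, y)
    resid = y - (ols.intercept + ols.slope * x)
    return {
        "slope": float(ols.slope),
        "slope_se": float(ols.stderr),
        "intercept": float(ols.intercept),
        "intercept_se": float(ols.intercept_stderr),
        "r2": float(ols.rvalue**2),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "n": len(x),
    }


def tissue_cva(
    spectra: np.ndarray,
    labels: np.ndarray,
    stride: int = 2,
    offset: int = 1,
    ridge: float = 1e-6,
) -> CanonicalProjection:
    """Canonical variate analysis of tissue type from (SNV) mean spectra.

    Bands are first subsampled (default: every 2nd wavelength).  Directions
    maximize between-group over within-group scatter, found from the
    generalized eigenproblem B v = lambda W v; the pooled within-group
    covariance is ridge-regularized by ``ridge * trace(W)/p`` whenever
    bands outnumber samples.  Wilks' lambda = prod 1/(1+lambda_i) over the
    nonzero eigenvalues (1 means no separation).
    """
    X = subsample_bands(np.asarray(spectra, dtype=float), stride, offset)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for CVA")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        sub = X[labels == g]
        mu = sub.mean(axis=0)
        centered = sub - mu
        W += centered.T @ centered
        B += len(sub) * np.outer(mu - grand, mu - grand)
    W += ridge * (np.trace(W) / p) * np.eye(p)

    eigvals, eigvecs = linalg.eigh(B, W)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_cv = min(2, p)
    # eigh(B, W) returns v with v' W v = 1; rescale so within-group score
    # variance is 1 — this metric makes scores affine-invariant in the data
    directions = eigvecs[:, :n_cv] * np.sqrt(n - len(groups))
    if directions.shape[1] < 2:  # degenerate single-band case
        directions = np.column_stack([directions, directions])
    scores = (X - grand) @ directions[:, :2]
    n_nonzero = min(len(groups) - 1, p)
    lam = np.clip(eigvals[:n_nonzero], 0.0, None)
    wilks = float(np.prod(1.0 / (1.0 + lam)))
    return CanonicalProjection(directions[:, :2], scores, wilks, labels)
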