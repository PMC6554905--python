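"""Partial least squares regression (NIPALS), VIP scores and fit reports.

PLSR projects multi-collinear spectra onto a small number of latent
variables (LVs) chosen to maximize covariance with the response, then
regresses on the scores.  This implementation is the classical NIPALS
algorithm for a single response, deflating X only:

    w_a = X'y / ||X'y||          (weights)
    t_a = X w_a                  (scores)
    p_a = X't_a / (t_a't_a)      (X loadings)
    q_a = y't_a / (t_a't_a)      (y loading)
    X  <- X - t_a p_a'           (deflation)

The regression vector on the (centered, optionally scaled) predictor scale
for A components is B_A = W_A (P_A' W_A)^{-1} q_A; per-LV coefficient
vectors are retained so cross-validation over an LV grid needs one fit.

Variable importance in projection for band j:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ),
    SSY_a = q_a^2 (t_a't_a),

whose squared values average to 1 over bands, making VIP >= 1 the natural
"more important than average" cutoff.

Report statistics follow chemometrics convention: R^2 is the squared
Pearson correlation between observed and predicted (the alternative
1 - SS_res/SS_tot definition is available via ``r2_method="ss"``), RMSE is
the root mean squared error, and validation slope/intercept come from the
ordinary least squares regression y_measured = a + b * y_predicted with
bias = mean(predicted - observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PLSModel", "ModelReport", "fit_plsr", "predict", "vip", "report"]

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    x_mean: np.ndarray
    x_sd: np.ndarray | None        # None when fit unscaled
    y_mean: float
    weights: np.ndarray            # (p, A)
    x_loadings: np.ndarray         # (p, A)
    y_loadings: np.ndarray         # (A,)
    scores: np.ndarray             # (n, A)
    n_lv: int
    coefs_per_lv: np.ndarray       # (p, A): column a-1 = coefficients using a LVs
    warnings: list = field(default_factory=list)
    pipeline: dict = field(default_factory=dict)  # preprocessing provenance

    @property
    def coef(self) -> np.ndarray:
        """Regression vector (centered/scaled predictor space) at the full LV count."""
        return self.coefs_per_lv[:, self.n_lv - 1]

    @property
    def n_bands(self) -> int:
        return self.weights.shape[0]


@dataclass
class ModelReport:
    """One row of fit statistics in the conventional table layout."""

    attribute: str = ""
    method: str = "PLSR"
    lv: int | None = None
    r2_cal: float = np.nan
    rmse_cal: float = np.nan
    n_cal: int = 0
    min_cal: float = np.nan
    max_cal: float = np.nan
    mean_cal: float = np.nan
    sd_cal: float = np.nan
    r2_val: float = np.nan
    rmse_val: float = np.nan
    n_val: int = 0
    min_val: float = np.nan
    max_val: float = np.nan
    mean_val: float = np.nan
    sd_val: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    slope: float = np.nan
    slope_se: float = np.nan
    bias: float = np.nan
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "extra"}
        row.update(self.extra)
        return row


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
    pipeline: dict | None = None,
) -> PLSModel:
    """Fit a single-response NIPALS PLSR with up to ``n_lv`` components.

    X is centered (and optionally unit-variance scaled); y is centered only.
    If the residual predictor matrix runs out of rank before ``n_lv``
    components, the model is truncated and a warning string is recorded on
    ``model.warnings``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)} values")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if np.std(y) == 0:
        raise ValueError("zero-variance response: nothing to regress on")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")

    warnings: list[str] = []
    max_rank = min(n - 1, p)
    if n_lv > max_rank:
        warnings.append(
            f"n_lv {n_lv} exceeds min(n-1, p) = {max_rank}; truncated"
        )
        n_lv = max_rank

    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if scale:
        x_sd = Xc.std(axis=0, ddof=1)
        x_sd[x_sd == 0] = 1.0
        Xc = Xc / x_sd
    else:
        x_sd = None
    y_mean = float(y.mean())
    yc = y - y_mean

    x_scale_ref = float(np.abs(Xc).max()) or 1.0
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xd, yd = Xc.copy(), yc.copy()
    a = 0
    for a in range(n_lv):
        # NIPALS inner loop; for a single response it converges in one pass
        u = yd
        w = np.zeros(p)
        t = np.zeros(n)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm <= tol * x_scale_ref:
                break
            w_new = w_new / norm
            t_new = Xd @ w_new
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), _EPS):
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
            u = yd  # single response: u stays y
        tt = float(t @ t)
        if tt <= (tol * x_scale_ref) ** 2 or np.linalg.norm(w) == 0:
            warnings.append(
                f"predictor residual exhausted after {a} components; truncated"
            )
            break
        W[:, a], T[:, a] = w, t
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        Xd = Xd - np.outer(t, P[:, a])
        a += 1
    n_kept = a
    if n_kept == 0:
        raise ValueError("no PLS component could be extracted (X has no variance)")
    W, P, T, q = W[:, :n_kept], P[:, :n_kept], T[:, :n_kept], q[:n_kept]

    # per-LV regression vectors: B_a = W_a (P_a' W_a)^{-1} q_a
    coefs = np.zeros((p, n_kept))
    PtW = P.T @ W
    for k in range(1, n_kept + 1):
        bk = np.linalg.solve(PtW[:k, :k], q[:k])
        coefs[:, k - 1] = W[:, :k] @ bk

    return PLSModel(
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        n_lv=n_kept,
        coefs_per_lv=coefs,
        warnings=warnings,
        pipeline=dict(pipeline or {}),
    )


def predict(model: PLSModel, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Predict responses; ``n_lv`` (<= model.n_lv) picks a reduced-LV model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_bands:
        raise ValueError(
            f"input has {X.shape[1]} bands but model was fit on {model.n_bands}"
        )
    if n_lv is None:
        n_lv = model.n_lv
    if not 1 <= n_lv <= model.n_lv:
        raise ValueError(f"n_lv must be in [1, {model.n_lv}], got {n_lv}")
    Xc = X - model.x_mean
    if model.x_sd is not None:
        Xc = Xc / model.x_sd
    return model.y_mean + Xc @ model.coefs_per_lv[:, n_lv - 1]


def vip(model: PLSModel) -> np.ndarray:
    """Per-band variable importance in projection; mean of squares equals 1."""
    W, T, q = model.weights, model.scores, model.y_loadings
    p, A = W.shape
    ssy = q**2 * np.einsum("ia,ia->a", T, T)  # explained y sum of squares per LV
    wnorm2 = np.sum(W**2, axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (W**2 / wnorm2) @ ssy
    total = float(ssy.sum())
    if total <= 0:
        return np.ones(p)
    return np.sqrt(p * contrib / total)


def _r2(y_obs: np.ndarray, y_pred: np.ndarray, method: str) -> float:
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        return np.nan
    if method == "pearson":
        return float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    if method == "ss":
        ss_res = float(np.sum((y_obs - y_pred) ** 2))
        ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown r2 method {method!r}")


def report(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    subsets: np.ndarray | list,
    lv: int | None = None,
    attribute: str = "",
    method: str = "PLSR",
    r2_method: str = "pearson",
) -> ModelReport:
    """Assemble calibration/validation statistics into one report row.

    ``subsets`` labels each sample "cal" or "val".  The validation
    regression y_measured = a + b * y_predicted (with standard errors) and
    bias are computed on the validation subset when present, otherwise on
    the calibration subset.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    subsets = np.asarray(subsets)
    if not (len(y_obs) == len(y_pred) == len(subsets)):
        raise ValueError("y_obs, y_pred and subsets must have equal lengths")
    if len(y_obs) < 3:
        raise ValueError("need at least 3 samples to report statistics")

    rep = ModelReport(attribute=attribute, method=method, lv=lv)
    for name in ("cal", "val"):
        sel = subsets == name
        n = int(sel.sum())
        setattr(rep, f"n_{name}", n)
        if n == 0:
            continue
        obs, pred = y_obs[sel], y_pred[sel]
        setattr(rep, f"r2_{name}", _r2(obs, pred, r2_method))
        setattr(rep, f"rmse_{name}", float(np.sqrt(np.mean((obs - pred) ** 2))))
        setattr(rep, f"min_{name}", float(obs.min()))
        setattr(rep, f"max_{name}", float(obs.max()))
        setattr(rep, f"mean_{name}", float(obs.mean()))
        setattr(rep, f"sd_{name}", float(obs.std(ddof=1)) if n > 1 else np.nan)

    reg_sel = subsets == ("val" if rep.n_val >= 3 else "cal")
    obs, pred = y_obs[reg_sel], y_pred[reg_sel]
    if np.ptp(pred) > 0:  # np.std can be > 0 on constant data from round-off
        ols = stats.linregress(pred, obs)
        rep.slope = float(ols.slope)
        rep.intercept = float(ols.intercept)
        rep.slope_se = float(ols.stderr)
        rep.intercept_se = float(ols.intercept_stderr)
    rep.bias = float(np.mean(pred - obs))
    return rep
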