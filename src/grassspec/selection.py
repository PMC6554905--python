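"""Model and wavelength selection for spectral PLSR.

Covers the selection machinery around the PLS core:

* plant-level calibration/validation splitting (two-thirds calibration);
* Monte-Carlo ten-fold cross-validation error curves over an LV grid;
* Adjusted Wold's R criterion for picking the LV count: the first LV k at
  which the ratio press(k+1)/press(k) reaches the threshold (1.0, or the
  more parsimonious 0.99) — further components no longer pay for
  themselves;
* CARS (competitive adaptive reweighted sampling) wavelength selection:
  Monte-Carlo PLS fits combined with an exponentially decreasing enforced
  retention schedule and coefficient-weighted resampling, keeping the
  subset with the lowest cross-validated RMSE;
* VIP-threshold wavelength selection;
* a uniform harness running eleven regression methods (four PLSR variants
  plus seven generic learners) and emitting comparable report rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pls
from .preprocess import subsample_bands

__all__ = [
    "CvCurve",
    "BandSubset",
    "split_calibration_validation",
    "mc_cv_curve",
    "adjusted_wold",
    "cars_select",
    "vip_select",
    "bands_to_ranges",
    "run_method",
    "run_all_methods",
    "METHODS",
]


@dataclass
class CvCurve:
    """Cross-validation error curve over an LV grid.

    ``press`` holds the pooled mean squared held-out error per LV (averaged
    over folds and Monte-Carlo replicates); ``rmse`` is its square root.
    """

    lv_grid: np.ndarray
    press: np.ndarray
    reps: int
    folds: int
    seed: int
    press_se: np.ndarray | None = None

    @property
    def rmse(self) -> np.ndarray:
        return np.sqrt(self.press)


@dataclass
class BandSubset:
    method: str
    selected: np.ndarray            # strictly increasing band positions
    criterion_value: float
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if self.selected.size == 0:
            raise ValueError("selected band subset must be non-empty")
        if np.any(np.diff(self.selected) <= 0):
            raise ValueError("selected band positions must be strictly increasing")


def split_calibration_validation(
    table: pd.DataFrame | np.ndarray | list,
    frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split plant ids into disjoint calibration/validation sets.

    Accepts a DataFrame with a ``plant_id`` column or a sequence of ids.
    The split is at plant level (every row of one plant stays on one side);
    calibration gets round(frac * n) plants, with both sides guaranteed
    non-empty.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must lie strictly in (0, 1), got {frac}")
    if isinstance(table, pd.DataFrame):
        ids = table["plant_id"].unique()
    else:
        ids = pd.unique(np.asarray(table))
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 plants to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_cal = int(round(frac * n))
    n_cal = min(max(n_cal, 1), n - 1)  # both sides non-empty
    return np.sort(ids[order[:n_cal]]), np.sort(ids[order[n_cal:]])


def mc_cv_curve(
    X: np.ndarray,
    y: np.ndarray,
    lv_max: int = 50,
    folds: int = 10,
    reps: int = 100,
    seed: int = 0,
) -> CvCurve:
    """Monte-Carlo k-fold cross-validation error per LV.

    Each replicate draws a fresh random fold partition; one PLS fit per
    training fold yields held-out predictions for every LV at once.  Errors
    are pooled as mean squared error over all held-out predictions (then
    rooted by the caller if RMSE is wanted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if folds > n:
        raise ValueError(f"folds {folds} exceeds sample count {n}")
    if lv_max < 1:
        raise ValueError("lv_max must be >= 1")
    rng = np.random.default_rng(seed)

    sq_sum = np.zeros(lv_max)
    counts = np.zeros(lv_max)
    rep_means = np.zeros((reps, lv_max))
    for r in range(reps):
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % folds
        rep_sq = np.zeros(lv_max)
        rep_n = np.zeros(lv_max)
        for f in range(folds):
            test = fold_of == f
            train = ~test
            model = pls.fit_plsr(X[train], y[train], n_lv=lv_max)
            Xc = X[test] - model.x_mean
            if model.x_sd is not None:
                Xc = Xc / model.x_sd
            preds = model.y_mean + Xc @ model.coefs_per_lv  # (n_test, A)
            errs = (preds - y[test, None]) ** 2
            a = model.n_lv
            rep_sq[:a] += errs.sum(axis=0)
            rep_n[:a] += test.sum()
            if a < lv_max:  # rank-truncated: best available model carries on
                rep_sq[a:] += errs[:, -1].sum()
                rep_n[a:] += test.sum()
        sq_sum += rep_sq
        counts += rep_n
        rep_means[r] = rep_sq / rep_n
    press = sq_sum / counts
    se = rep_means.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else None
    return CvCurve(np.arange(1, lv_max + 1), press, reps, folds, seed, se)


def adjusted_wold(curve: CvCurve | np.ndarray, threshold: float = 1.0) -> int:
    """Adjusted Wold's R criterion: smallest LV k with press(k+1)/press(k) >= threshold.

    A ratio at or above the threshold means the next component no longer
    reduces the cross-validation error (threshold 1.0) or reduces it by
    less than 1% (threshold 0.99).  If every ratio stays below the
    threshold the full grid length is returned.
    """
    press = curve.press if isinstance(curve, CvCurve) else np.asarray(curve, dtype=float)
    if len(press) < 2:
        raise ValueError("curve must have at least 2 LVs")
    ratios = press[1:] / press[:-1]
    hits = np.nonzero(ratios >= threshold)[0]
    if hits.size == 0:
        return len(press)
    return int(hits[0]) + 1  # ratio index k-1 corresponds to selecting k LVs


def _cv_rmse(X: np.ndarray, y: np.ndarray, n_lv: int, folds: int, rng) -> float:
    """Plain k-fold CV RMSE of a PLS model at a fixed LV count."""
    n = len(y)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    sq, m = 0.0, 0
    for f in range(folds):
        test = fold_of == f
        model = pls.fit_plsr(X[~test], y[~test], n_lv=n_lv)
        pred = pls.predict(model, X[test])
        sq += float(np.sum((pred - y[test]) ** 2))
        m += int(test.sum())
    return float(np.sqrt(sq / m))


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    mc_ratio: float = 0.8,
    folds: int = 5,
    seed: int = 0,
    n_lv: int = 10,
) -> BandSubset:
    """Competitive adaptive reweighted sampling wavelength selection.

    Run i fits PLS on a random ``mc_ratio`` sample of the calibration rows
    restricted to the surviving bands and ranks bands by |regression
    coefficient|.  An exponentially decreasing schedule r_i = a e^{-k i},
    calibrated so r_1 = 1 and r_{n_runs} = 2/p, sets the enforced retention
    fraction; adaptive reweighted sampling then draws the retained set with
    probability proportional to |coefficient|.  Every run's subset is scored
    by k-fold CV RMSE and the subset with the minimum RMSE wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 bands")
    rng = np.random.default_rng(seed)

    if n_runs == 1:
        ratios = np.array([1.0])
    else:
        k = np.log(p / 2.0) / (n_runs - 1)
        a = np.exp(k)
        ratios = a * np.exp(-k * np.arange(1, n_runs + 1))

    current = np.arange(p)
    best: tuple[float, np.ndarray] | None = None
    trace: list[tuple[int, int, float]] = []
    truncated = False
    for i in range(n_runs):
        if current.size < 2:
            truncated = True
            break
        m = max(2, int(round(mc_ratio * n)))
        rows = rng.choice(n, size=m, replace=False)
        sub = X[np.ix_(rows, current)]
        model = pls.fit_plsr(sub, y[rows], n_lv=min(n_lv, current.size, m - 1))
        coef = np.abs(model.coef)

        n_keep = max(2, int(round(ratios[i] * p)))
        n_keep = min(n_keep, current.size)
        forced = current[np.argsort(coef)[::-1][:n_keep]]
        forced_coef = coef[np.argsort(coef)[::-1][:n_keep]]

        if ratios[i] >= 1.0:
            # nothing is eliminated on a full-retention run
            subset = np.sort(forced)
        else:
            # adaptive reweighted sampling within the enforced set
            weights = forced_coef / forced_coef.sum() if forced_coef.sum() > 0 else None
            drawn = rng.choice(forced, size=n_keep, replace=True, p=weights)
            subset = np.unique(drawn)
            if subset.size < 2:
                subset = np.sort(forced[:2])

        rmse = _cv_rmse(X[:, subset], y, min(n_lv, subset.size, n - 2), folds, rng)
        trace.append((i + 1, int(subset.size), rmse))
        if best is None or rmse < best[0]:
            best = (rmse, subset)
        current = subset
    if best is None:
        raise ValueError("CARS eliminated all bands before scoring any subset")
    result = BandSubset("CARS", np.sort(best[1]), best[0], trace)
    if truncated:
        result.trace.append(("warning", "all bands eliminated before n_runs", None))
    return result


def vip_select(model: pls.PLSModel, threshold: float = 1.0) -> BandSubset:
    """Bands whose VIP score is at least ``threshold``."""
    scores = pls.vip(model)
    selected = np.nonzero(scores >= threshold)[0]
    if selected.size == 0:
        raise ValueError(
            f"no band reaches VIP threshold {threshold}; max VIP = {scores.max():.4f}"
        )
    return BandSubset("VIP", selected, float(threshold))


def bands_to_ranges(selected: np.ndarray, wavelengths: np.ndarray) -> list[tuple[float, float]]:
    """Summarize contiguous selected band runs as (lo_nm, hi_nm) ranges."""
    selected = np.asarray(selected, dtype=int)
    wl = np.asarray(wavelengths, dtype=float)
    ranges = []
    start = prev = selected[0]
    for b in selected[1:]:
        if b != prev + 1:
            ranges.append((float(wl[start]), float(wl[prev])))
            start = b
        prev = b
    ranges.append((float(wl[start]), float(wl[prev])))
    return ranges


METHODS = (
    "PLSR-AW",
    "PLSR-AW0.99",
    "PLSR-CARS",
    "PLSR-VIP",
    "GPR",
    "SVM",
    "RF",
    "MLR",
    "SMLR",
    "LASSO",
    "RMLR",
)

# MLR-family methods cannot invert a 235-band Gram matrix with ~130 samples;
# they operate on an every-5th-band subsampled basis.
_MLR_STRIDE = 5


def _stepwise_ols(X: np.ndarray, y: np.ndarray, p_enter: float = 0.05, p_exit: float = 0.10):
    """Forward-backward stepwise OLS on column indices, by partial-F p-values."""
    import statsmodels.api as sm

    n, p = X.shape
    included: list[int] = []
    while True:
        changed = False
        excluded = [j for j in range(p) if j not in included]
        if excluded and len(included) < n - 2:
            pvals = {}
            for j in excluded:
                cols = included + [j]
                fit = sm.OLS(y, sm.add_constant(X[:, cols])).fit()
                pvals[j] = fit.pvalues[-1]
            best_j = min(pvals, key=pvals.get)
            if pvals[best_j] < p_enter:
                included.append(best_j)
                changed = True
        if included:
            fit = sm.OLS(y, sm.add_constant(X[:, included])).fit()
            worst = int(np.argmax(fit.pvalues[1:]))
            if fit.pvalues[1:][worst] > p_exit:
                included.pop(worst)
                changed = True
        if not changed:
            break
    return included


def run_method(
    method: str,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
    attribute: str = "",
    cv_reps: int = 20,
    lv_max: int = 25,
    cars_runs: int = 50,
) -> pls.ModelReport:
    """Fit one named method and report uniform calibration/validation statistics.

    PLSR variants use this package's NIPALS core; the seven generic learners
    delegate to standard scikit-learn / statsmodels implementations behind
    this adapter.
    """
    key = method.upper()
    if key not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    lv_max = min(lv_max, len(y_cal) - 2, X_cal.shape[1])
    lv = None

    def _pls_aw(Xc, Xv, threshold):
        curve = mc_cv_curve(Xc, y_cal, lv_max=lv_max, folds=10, reps=cv_reps, seed=seed)
        k = adjusted_wold(curve, threshold)
        model = pls.fit_plsr(Xc, y_cal, n_lv=k)
        return model, pls.predict(model, Xc), pls.predict(model, Xv), model.n_lv

    if key == "PLSR-AW":
        _, pred_cal, pred_val, lv = _pls_aw(X_cal, X_val, 1.0)
    elif key == "PLSR-AW0.99":
        _, pred_cal, pred_val, lv = _pls_aw(X_cal, X_val, 0.99)
    elif key == "PLSR-CARS":
        subset = cars_select(X_cal, y_cal, n_runs=cars_runs, seed=seed)
        _, pred_cal, pred_val, lv = _pls_aw(
            X_cal[:, subset.selected], X_val[:, subset.selected], 1.0
        )
    elif key == "PLSR-VIP":
        full = pls.fit_plsr(X_cal, y_cal, n_lv=min(10, lv_max))
        subset = vip_select(full)
        _, pred_cal, pred_val, lv = _pls_aw(
            X_cal[:, subset.selected], X_val[:, subset.selected], 1.0
        )
    elif key == "GPR":
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        kernel = 1.0 * RBF(
            length_scale=np.sqrt(X_cal.shape[1]),
            length_scale_bounds=(1e-2, 1e4),
        ) + WhiteKernel(1e-2, noise_level_bounds=(1e-10, 1e2))
        gpr = make_pipeline(
            StandardScaler(),
            GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                     random_state=seed),
        )
        gpr.fit(X_cal, y_cal)
        pred_cal, pred_val = gpr.predict(X_cal), gpr.predict(X_val)
    elif key == "SVM":
        from sklearn.compose import TransformedTargetRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR

        svr = TransformedTargetRegressor(
            make_pipeline(StandardScaler(), SVR(C=100.0, epsilon=1e-3)),
            transformer=StandardScaler(),
        )
        svr.fit(X_cal, y_cal)
        pred_cal, pred_val = svr.predict(X_cal), svr.predict(X_val)
    elif key == "RF":
        from sklearn.ensemble import RandomForestRegressor

        rf = RandomForestRegressor(n_estimators=300, random_state=seed, n_jobs=1)
        rf.fit(X_cal, y_cal)
        pred_cal, pred_val = rf.predict(X_cal), rf.predict(X_val)
    elif key in ("MLR", "SMLR", "RMLR"):
        import statsmodels.api as sm

        Xc = subsample_bands(X_cal, stride=_MLR_STRIDE, offset=0)
        Xv = subsample_bands(X_val, stride=_MLR_STRIDE, offset=0)
        if key == "SMLR":
            cols = _stepwise_ols(Xc, y_cal)
            if not cols:
                cols = [int(np.argmax(np.abs(np.corrcoef(Xc.T, y_cal)[-1, :-1])))]
            Xc, Xv = Xc[:, cols], Xv[:, cols]
        design_c, design_v = sm.add_constant(Xc), sm.add_constant(Xv, has_constant="add")
        if key == "RMLR":
            fit = sm.RLM(y_cal, design_c, M=sm.robust.norms.HuberT()).fit()
        else:
            fit = sm.OLS(y_cal, design_c).fit()
        pred_cal, pred_val = fit.predict(design_c), fit.predict(design_v)
    elif key == "LASSO":
        from sklearn.linear_model import LassoCV
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        lasso = make_pipeline(
            StandardScaler(), LassoCV(cv=5, random_state=seed, max_iter=5000)
        )
        lasso.fit(X_cal, y_cal)
        pred_cal, pred_val = lasso.predict(X_cal), lasso.predict(X_val)

    y_all = np.concatenate([y_cal, y_val])
    pred_all = np.concatenate([np.asarray(pred_cal), np.asarray(pred_val)])
    subsets = np.array(["cal"] * len(y_cal) + ["val"] * len(y_val))
    return pls.report(y_all, pred_all, subsets, lv=lv, attribute=attribute, method=key)


def run_all_methods(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
    attribute: str = "",
    methods: tuple = METHODS,
    **kwargs,
) -> pd.DataFrame:
    """Run the full method comparison; one report row per method."""
    rows = [
        run_method(m, X_cal, y_cal, X_val, y_val, seed=seed, attribute=attribute, **kwargs).to_row()
        for m in methods
    ]
    return pd.DataFrame(rows)
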