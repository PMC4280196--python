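"""Partial least-squares regression (PLS1) with LOOCV model selection.

The calibration model is mean-centred NIPALS PLS with a single response
(total nitrogen content, % dry basis).  For one response NIPALS is
non-iterative: each latent variable's weight vector is the (normalised)
X-residual / y-residual covariance, followed by deflation of both blocks.
The fitted model is exposed both in latent form (weights W, loadings P,
y-loadings q) and as the equivalent linear predictor

    y_hat = b0 + x . b,      b = W (P'W)^{-1} q,   b0 = mean(y) - mean(x) . b

which is what pixel-wise chemical imaging applies.

Latent-variable count is chosen by leave-one-out cross-validation
(LOOCV): for each left-out sample a model is fitted on the rest and the
RMSECV curve over component counts is accumulated; the minimiser wins,
ties going to fewer components.  Model quality is reported as the triad
of Pearson correlation R and root-mean-square error on the calibration,
cross-validation and prediction sets (R_C/RMSEC, R_CV/RMSECV, R_P/RMSEP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .hypercube_io import SpectraTable
from .variable_selection import FrogResult, rank_wavelengths

__all__ = [
    "PLSModel",
    "FitMetrics",
    "ModelComparison",
    "fit_plsr",
    "loocv_select_lvs",
    "evaluate",
    "full_vs_selected_report",
    "elimination_percentage",
    "WHOLE_PLANT_BENCHMARK",
]


# Published benchmark metrics for whole-plant nitrogen PLSR models — the
# full-spectrum model (F-PLSR, 460 wavelengths) versus the model on the
# 8 frog-selected wavelengths (RF-PLSR).  Triads are
# (R_C, RMSEC, R_CV, RMSECV, R_P, RMSEP); RMSE in TNC %.  Used as a
# magnitude reference and for delta arithmetic in reports.
WHOLE_PLANT_BENCHMARK: dict[str, dict[str, float]] = {
    "F-PLSR": {"n_wavelengths": 460, "n_lvs": 6,
               "R_C": 0.904, "RMSEC": 0.388,
               "R_CV": 0.893, "RMSECV": 0.409,
               "R_P": 0.908, "RMSEP": 0.351},
    "RF-PLSR": {"n_wavelengths": 8, "n_lvs": 4,
                "R_C": 0.878, "RMSEC": 0.451,
                "R_CV": 0.874, "RMSECV": 0.468,
                "R_P": 0.876, "RMSEP": 0.426},
}


# ---------------------------------------------------------------------------
# NIPALS PLS1 core
# ---------------------------------------------------------------------------

def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_lvs: int,
                 eps: float = 1e-12):
    """Mean-centred PLS1.  Returns (x_mean, y_mean, W, P, q, achieved).

    ``W`` (p, a) weights, ``P`` (p, a) x-loadings, ``q`` (a,) y-loadings on
    centred data.  Stops early (achieved < n_lvs) when the residual carries
    no usable covariance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean
    scale = max(float(np.abs(E).max()), 1.0) * max(float(np.abs(f).max()), 1.0)

    W = np.empty((p, n_lvs))
    P = np.empty((p, n_lvs))
    q = np.empty(n_lvs)
    a = 0
    for _ in range(n_lvs):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= eps * scale:
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        pl = E.T @ t / tt
        ql = float(f @ t) / tt
        E -= np.outer(t, pl)
        f = f - ql * t
        W[:, a], P[:, a], q[a] = w, pl, ql
        a += 1
    return x_mean, y_mean, W[:, :a], P[:, :a], q[:a], a


def _pls1_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vector b = W (P'W)^{-1} q on centred data."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    # P'W is unit upper triangular for NIPALS; solve rather than invert.
    R = P.T @ W
    return W @ solve_triangular(R, q, lower=False)


def pls1_fit_predict(X_train, y_train, X_test, n_lvs: int) -> np.ndarray:
    """Fast fit-and-predict used inside cross-validation loops."""
    xm, ym, W, P, q, _ = _nipals_pls1(X_train, y_train, n_lvs)
    b = _pls1_coefficients(W, P, q)
    return ym + (np.asarray(X_test, dtype=float) - xm) @ b


def cv_rmse(X, y, n_lvs: int, n_folds: int = 5) -> float:
    """K-fold cross-validated RMSE of a PLS1 model (contiguous folds,
    deterministic)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} samples for {n_folds}-fold CV")
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    sse = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        tr = np.r_[0:lo, hi:n]
        a = min(n_lvs, len(tr) - 1, X.shape[1])
        pred = pls1_fit_predict(X[tr], y[tr], X[lo:hi], a)
        sse += float(((pred - y[lo:hi]) ** 2).sum())
    return float(np.sqrt(sse / n))


# ---------------------------------------------------------------------------
# Public model surface
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS1 calibration model.

    Carries the latent structure (weights/loadings on centred data) and
    the equivalent linear form used for pixel-wise prediction.
    """

    wavelengths: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray          # (p, a)
    x_loadings: np.ndarray       # (p, a)
    y_loadings: np.ndarray       # (a,)
    n_lvs: int

    @property
    def coefficients(self) -> np.ndarray:
        """Per-wavelength slope vector b of the linear form."""
        return _pls1_coefficients(self.weights, self.x_loadings, self.y_loadings)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict via the linear form, y = b0 + X b."""
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def predict_latent(self, X: np.ndarray) -> np.ndarray:
        """Predict via scores T = (X - mean) W (P'W)^{-1}, y = ymean + T q."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        if self.weights.shape[1] == 0:
            return np.full(Xc.shape[0], self.y_mean)
        R = self.x_loadings.T @ self.weights
        T = np.linalg.solve(R.T, (Xc @ self.weights).T).T
        return self.y_mean + T @ self.y_loadings

    def to_dict(self) -> dict:
        b = self.coefficients
        return {
            "n_lvs": int(self.n_lvs),
            "intercept": float(self.intercept),
            "wavelengths_nm": [float(w) for w in self.wavelengths],
            "coefficients": [float(c) for c in b],
        }


@dataclass
class FitMetrics:
    """R/RMSE triad over calibration, cross-validation, and prediction."""

    n_lvs: int
    n_calibration: int
    n_prediction: int
    R_C: float = np.nan
    RMSEC: float = np.nan
    R_CV: float = np.nan
    RMSECV: float = np.nan
    R_P: float = np.nan
    RMSEP: float = np.nan
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.__dict__.items()}


def fit_plsr(X_cal: np.ndarray, y_cal: np.ndarray, n_lvs: int,
             wavelengths: np.ndarray | None = None) -> PLSModel:
    """Fit a mean-centred PLS1 model with ``n_lvs`` latent variables.

    If the residual rank is exhausted before ``n_lvs`` components the model
    is returned with the achievable count and a warning.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    n, p = X_cal.shape
    if n < 2:
        raise ValueError("need at least two calibration samples")
    if not 1 <= n_lvs <= min(n - 1, p):
        raise ValueError(
            f"n_lvs must be in [1, {min(n - 1, p)}] for n={n}, p={p}")
    if not (np.isfinite(X_cal).all() and np.isfinite(y_cal).all()):
        raise ValueError("non-finite values in calibration data")
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    xm, ym, W, P, q, a = _nipals_pls1(X_cal, y_cal, n_lvs)
    if a < n_lvs:
        warnings.warn(
            f"requested {n_lvs} latent variables but data supports only {a}; "
            "fitting with the achievable count", stacklevel=2)
    return PLSModel(wavelengths=np.asarray(wavelengths, dtype=float),
                    x_mean=xm, y_mean=ym, weights=W, x_loadings=P,
                    y_loadings=q, n_lvs=max(a, 0))


def loocv_select_lvs(X_cal, y_cal, max_lvs: int = 20) -> tuple[int, np.ndarray]:
    """Leave-one-out selection of the latent-variable count.

    Returns ``(n_lvs, rmsecv_curve)`` where ``rmsecv_curve[a-1]`` is the
    LOOCV RMSE with ``a`` components.  NIPALS components are nested, so one
    fit per left-out sample yields the whole curve.  Ties break toward
    fewer components.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    n, p = X_cal.shape
    if n < 3:
        raise ValueError("LOOCV needs at least three samples")
    feasible = min(n - 2, p)
    if max_lvs > feasible:
        warnings.warn(
            f"max_lvs={max_lvs} exceeds the feasible count {feasible}; "
            "clipping", stacklevel=2)
        max_lvs = feasible
    sse = np.zeros(max_lvs)
    for i in range(n):
        tr = np.r_[0:i, i + 1:n]
        xm, ym, W, P, q, a = _nipals_pls1(X_cal[tr], y_cal[tr], max_lvs)
        xc = X_cal[i] - xm
        # nested predictions for every component count
        for k in range(1, max_lvs + 1):
            kk = min(k, a)
            b = _pls1_coefficients(W[:, :kk], P[:, :kk], q[:kk])
            sse[k - 1] += (ym + xc @ b - y_cal[i]) ** 2
    curve = np.sqrt(sse / n)
    n_lvs = int(np.argmin(curve)) + 1      # argmin is first minimum: fewest LVs
    return n_lvs, curve


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0 or len(a) < 2:
        return 0.0, True                   # degenerate: correlation undefined
    return float(np.corrcoef(a, b)[0, 1]), False


def evaluate(model: PLSModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """(R, RMSE, degenerate_flag) of ``model`` on a labelled set.

    R is the Pearson correlation between predicted and measured values; a
    zero-variance vector makes it undefined and is reported as 0 with the
    degenerate flag set.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.wavelengths):
        raise ValueError(
            f"X has {X.shape[1]} wavelengths but the model expects "
            f"{len(model.wavelengths)}")
    pred = model.predict(X)
    r, degenerate = _pearson(pred, y)
    rmse = float(np.sqrt(np.mean((pred - np.asarray(y, dtype=float)) ** 2)))
    return r, rmse, degenerate


def calibrate_and_evaluate(table: SpectraTable, cal_idx, pred_idx,
                           max_lvs: int = 20,
                           n_lvs: int | None = None) -> tuple[PLSModel, FitMetrics]:
    """Fit on the calibration rows (LV count by LOOCV unless given) and
    report the full R/RMSE triad."""
    Xc, yc = table.X[cal_idx], table.y[cal_idx]
    if n_lvs is None:
        n_lvs, curve = loocv_select_lvs(Xc, yc, max_lvs=max_lvs)
    else:
        _, curve = loocv_select_lvs(Xc, yc, max_lvs=max(n_lvs, 1))
    model = fit_plsr(Xc, yc, n_lvs, wavelengths=table.wavelengths)

    m = FitMetrics(n_lvs=model.n_lvs, n_calibration=len(cal_idx),
                   n_prediction=len(pred_idx))
    m.R_C, m.RMSEC, deg_c = evaluate(model, Xc, yc)
    m.RMSECV = float(curve[min(model.n_lvs, len(curve)) - 1])
    # LOOCV predictions for R_CV
    n = len(yc)
    cv_pred = np.empty(n)
    for i in range(n):
        tr = np.r_[0:i, i + 1:n]
        cv_pred[i] = pls1_fit_predict(Xc[tr], yc[tr], Xc[i:i + 1],
                                      min(model.n_lvs, len(tr) - 1))[0]
    m.R_CV, deg_cv = _pearson(cv_pred, yc)
    deg_p = False
    if len(pred_idx):
        m.R_P, m.RMSEP, deg_p = evaluate(model, table.X[pred_idx],
                                         table.y[pred_idx])
    m.degenerate = bool(deg_c or deg_cv or deg_p)
    return model, m


def elimination_percentage(p_full: int, k: int) -> float:
    """Percentage of variables eliminated when moving from ``p_full``
    wavelengths to ``k``: 100 (p_full - k) / p_full."""
    if not 1 <= k < p_full:
        raise ValueError("k must satisfy 1 <= k < p_full")
    return 100.0 * (p_full - k) / p_full


@dataclass
class ModelComparison:
    """Full-spectrum vs selected-wavelength model comparison record."""

    full_metrics: FitMetrics
    selected_metrics: FitMetrics
    full_model: PLSModel
    selected_model: PLSModel
    selected_wavelengths: np.ndarray
    elimination_percent: float

    def as_dict(self) -> dict:
        return {
            "F-PLSR": self.full_metrics.as_dict(),
            "RF-PLSR": self.selected_metrics.as_dict(),
            "selected_wavelengths_nm": [float(w) for w in self.selected_wavelengths],
            "elimination_percent": float(self.elimination_percent),
        }


def full_vs_selected_report(table: SpectraTable, cal_idx, pred_idx,
                            frog_result: FrogResult, k: int,
                            max_lvs: int = 20) -> ModelComparison:
    """Fit and compare F-PLSR (all wavelengths) against RF-PLSR (the top-k
    frog-ranked wavelengths), both calibrated on the same split."""
    p_full = table.n_wavelengths
    if k >= p_full:
        raise ValueError(f"k ({k}) must be < number of wavelengths ({p_full})")
    full_model, full_m = calibrate_and_evaluate(table, cal_idx, pred_idx,
                                                max_lvs=max_lvs)
    sel_wl = rank_wavelengths(frog_result, k)
    cols = np.sort([int(np.argmin(np.abs(table.wavelengths - w)))
                    for w in sel_wl])
    sub = SpectraTable(X=table.X[:, cols], y=table.y,
                       wavelengths=table.wavelengths[cols],
                       sample_ids=table.sample_ids, organs=table.organs,
                       positions=table.positions)
    sel_model, sel_m = calibrate_and_evaluate(sub, cal_idx, pred_idx,
                                              max_lvs=min(max_lvs, k))
    return ModelComparison(
        full_metrics=full_m, selected_metrics=sel_m,
        full_model=full_model, selected_model=sel_model,
        selected_wavelengths=np.asarray(sel_wl, dtype=float),
        elimination_percent=elimination_percentage(p_full, k),
    )
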