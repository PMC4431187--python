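"""NIPALS PLS1 regression with PRESS-based latent-factor selection.

The model is the classic univariate-response NIPALS decomposition: predictors
and response are mean-centred (no variance scaling — absorbance variables
share units), components are extracted sequentially as

    w_a = X_a' y_a / ||X_a' y_a||        (weights)
    t_a = X_a w_a                         (scores)
    p_a = X_a' t_a / (t_a' t_a)           (x-loadings)
    q_a = y_a' t_a / (t_a' t_a)           (y-loading)
    X_{a+1} = X_a - t_a p_a',   y_{a+1} = y_a - q_a t_a

and the regression vector is ``b = W (P'W)^{-1} q``. For a single response
the inner NIPALS iteration converges in one step, so the extraction above is
exact, not iterative.

The number of factors is chosen by leave-one-out cross-validation: PRESS(a)
is the sum of squared LOO prediction errors with ``a`` components, and the
selected A is the global PRESS minimiser (ties to the smaller A).
``loo_press`` runs the identical algorithm in its sample-space (Gram) form,
which makes the exhaustive interval searches affordable; the two forms are
algebraically the same and are cross-checked in the test suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import ReferenceSet, SpectraSet
from .sampling import SplitResult

__all__ = ["PLSModel", "CVCurve", "ModelMetrics", "fit_pls", "predict",
           "loo_press", "evaluate"]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model for one analyte."""

    analyte: str
    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray  # regression vector b, length = number of masked variables
    mask: np.ndarray | None = None  # boolean over the full variable axis
    weights: np.ndarray | None = None  # W (p x A)
    x_loadings: np.ndarray | None = None  # P (p x A)
    y_loadings: np.ndarray | None = None  # q (A,)

    @property
    def n_input_variables(self) -> int:
        """Width of the matrices this model predicts from (pre-masking)."""
        return int(self.mask.size) if self.mask is not None else int(self.coef.size)


def _nipals_pls1(
    xc: np.ndarray, yc: np.ndarray, a: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequential NIPALS extraction of ``a`` components from centred data.

    Raises if the requested number of components exceeds the effective rank
    of the (X, y) covariance sequence.
    """
    n, p = xc.shape
    w_all = np.empty((p, a))
    p_all = np.empty((p, a))
    q_all = np.empty(a)
    x = xc.copy()
    y = yc.copy()
    scale = np.linalg.norm(xc) * np.linalg.norm(yc)
    for k in range(a):
        w = x.T @ y
        wn = np.linalg.norm(w)
        if wn <= _RANK_TOL * max(scale, 1e-300):
            raise ValueError(
                f"requested {a} factors but the data support only {k} "
                "(X'y residual vanished)"
            )
        w /= wn
        t = x @ w
        tt = float(t @ t)
        pl = x.T @ t / tt
        q = float(y @ t) / tt
        x -= np.outer(t, pl)
        y -= q * t
        w_all[:, k], p_all[:, k], q_all[k] = w, pl, q
    return w_all, p_all, q_all


def fit_pls(
    x: np.ndarray | SpectraSet,
    y: np.ndarray,
    n_factors: int,
    mask: np.ndarray | None = None,
    analyte: str = "y",
    keep_components: bool = True,
) -> PLSModel:
    """Fit a NIPALS PLS1 model with ``n_factors`` latent factors.

    ``mask`` restricts the model to a boolean subset of variables (interval
    models); prediction still accepts full-width matrices. Centring only, no
    autoscaling. ``keep_components=False`` drops W/P/q to save memory (used
    for large ensembles); the regression vector is kept either way.
    """
    xm = x.absorbance if isinstance(x, SpectraSet) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if xm.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != xm.shape[1]:
            raise ValueError("mask length must match the number of variables")
        # keep C order so masked and unmasked fits are bit-identical
        xm = np.ascontiguousarray(xm[:, mask])
    n, p = xm.shape
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors > min(n - 1, p):
        raise ValueError(
            f"n_factors={n_factors} exceeds min(N-1, P) = {min(n - 1, p)}"
        )
    if np.ptp(y) == 0:
        raise ValueError("response y has zero variance")
    x_mean = xm.mean(axis=0)
    y_mean = float(y.mean())
    w_all, p_all, q_all = _nipals_pls1(xm - x_mean, y - y_mean, n_factors)
    coef = w_all @ np.linalg.solve(p_all.T @ w_all, q_all)
    return PLSModel(
        analyte=analyte,
        n_factors=n_factors,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        mask=mask,
        weights=w_all if keep_components else None,
        x_loadings=p_all if keep_components else None,
        y_loadings=q_all if keep_components else None,
    )


def predict(model: PLSModel, x: np.ndarray | SpectraSet) -> np.ndarray:
    """Predict concentrations; applies the stored mask and centring."""
    xm = x.absorbance if isinstance(x, SpectraSet) else np.asarray(x, dtype=float)
    single = xm.ndim == 1
    xm = np.atleast_2d(xm)
    if xm.shape[1] != model.n_input_variables:
        raise ValueError(
            f"X has {xm.shape[1]} variables but the model expects "
            f"{model.n_input_variables} (wavelength-grid mismatch)"
        )
    if model.mask is not None:
        xm = np.ascontiguousarray(xm[:, model.mask])
    out = model.y_mean + (xm - model.x_mean) @ model.coef
    return out[0] if single else out


@dataclass
class CVCurve:
    """Leave-one-out PRESS as a function of the number of latent factors."""

    press: np.ndarray  # PRESS(a) for a = 1..len(press)
    n: int  # number of LOO folds (= calibration samples)
    a_max: int  # requested ceiling
    selected: int = field(init=False)

    def __post_init__(self) -> None:
        self.press = np.asarray(self.press, dtype=float)
        # global minimiser, ties to the smaller factor count
        self.selected = int(np.argmin(self.press)) + 1

    @property
    def rmsecv(self) -> np.ndarray:
        return np.sqrt(self.press / self.n)

    def parsimonious(self, tol: float = 0.02) -> int:
        """Smallest factor count whose PRESS is within ``tol`` of the
        minimum — a conservative alternative to the strict argmin."""
        threshold = (1.0 + tol) * float(self.press.min())
        return int(np.argmax(self.press <= threshold)) + 1

    @property
    def selected_rmsecv(self) -> float:
        return float(self.rmsecv[self.selected - 1])


def _loo_press_gram(gram: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """LOO PRESS(a), a = 1..a_max, from the raw (uncentred) Gram matrix.

    Kernel form of NIPALS PLS1: every fold's model lives in sample space, so
    only the fold's double-centred Gram submatrix is needed. Folds whose
    residual covariance vanishes (rank exhausted) freeze their predictions;
    the PRESS tail then stays constant so the argmin tie-break still favours
    the smaller factor count.
    """
    n = y.size
    m = n - 1
    idx = np.array([[j for j in range(n) if j != i] for i in range(n)])
    gf = gram[idx[:, :, None], idx[:, None, :]]  # (n, m, m) fold Grams
    gi = gram[idx, np.arange(n)[:, None]]  # (n, m): X_fold . x_heldout
    yf = y[idx]
    y_mean = yf.mean(axis=1)
    yf = yf - y_mean[:, None]
    rowm = gf.mean(axis=2)
    colm = gf.mean(axis=1)
    allm = rowm.mean(axis=1)
    gc = gf - rowm[:, :, None] - colm[:, None, :] + allm[:, None, None]
    k = gi - rowm
    k = k - k.mean(axis=1, keepdims=True)

    pred = y_mean.copy()
    press = np.empty(a_max)
    active = np.ones(n, dtype=bool)
    scale0 = None
    # PLS scores are mutually orthogonal, so instead of deflating each fold
    # Gram explicitly we keep the original centred Gram and project every
    # G-product against the accumulated score vectors:
    #   G_a v = Q G (Q v) with Q = I - sum_j t_j t_j' / (t_j' t_j),
    # and both y_a and t_a already lie in Q's range.
    t_hist = np.zeros((n, m, a_max))  # scores scaled to unit t't
    n_hist = 0

    def _deflated_matvec(v: np.ndarray) -> np.ndarray:
        out = np.matmul(gc, v[:, :, None])[:, :, 0]
        if n_hist:
            th = t_hist[:, :, :n_hist]
            out -= np.einsum("bma,ba->bm", th, np.einsum("bma,bm->ba", th, out))
        return out

    for a in range(a_max):
        s = _deflated_matvec(yf)
        nrm2 = np.einsum("bi,bi->b", yf, s)  # = ||X_a' y_a||^2
        if scale0 is None:
            scale0 = np.maximum(nrm2, 1e-300)
        active = active & (nrm2 > 1e-24 * scale0)
        if not active.any():
            press[a:] = press[a - 1] if a > 0 else float(((y - pred) ** 2).sum())
            break
        nrm = np.sqrt(np.where(active, nrm2, 1.0))
        t = np.where(active[:, None], s / nrm[:, None], 0.0)
        tt = np.einsum("bi,bi->b", t, t)
        tt_safe = np.where(active, tt, 1.0)
        qa = np.einsum("bi,bi->b", yf, t) / tt_safe
        t0 = np.where(active, np.einsum("bi,bi->b", k, yf) / nrm, 0.0)
        pred = pred + qa * t0
        gt = _deflated_matvec(t)
        k = k - (t0 / tt_safe)[:, None] * gt
        k = k - t * (np.einsum("bi,bi->b", t, k) / tt_safe)[:, None]
        yf = yf - qa[:, None] * t
        t_hist[:, :, n_hist] = t / np.sqrt(tt_safe)[:, None]
        n_hist += 1
        press[a] = float(((y - pred) ** 2).sum())
    return press


def loo_press(
    x: np.ndarray | SpectraSet,
    y: np.ndarray,
    a_max: int = 10,
    gram: np.ndarray | None = None,
) -> CVCurve:
    """Leave-one-out PRESS curve and factor selection.

    ``a_max`` is clipped (with a logged warning) to N-2 — a fold holds N-1
    samples, supporting at most N-2 centred components — and to the number of
    variables. A precomputed raw Gram matrix ``X @ X.T`` may be supplied.
    """
    xm = x.absorbance if isinstance(x, SpectraSet) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = xm.shape
    if n < 3:
        raise ValueError("leave-one-out factor selection needs at least 3 samples")
    ceiling = min(n - 2, p)
    if a_max > ceiling:
        logger.warning(
            "a_max=%d exceeds what %d samples x %d variables support; "
            "clipping to %d", a_max, n, p, ceiling,
        )
        a_max = ceiling
    if gram is None:
        gram = xm @ xm.T
    press = _loo_press_gram(gram, y, a_max)
    return CVCurve(press=press, n=n, a_max=a_max)


@dataclass
class ModelMetrics:
    """The standard calibration / cross-validation / prediction report.

    RMSE values are in the response units (mg/mL here); R2 is
    ``1 - SS_res / SS_tot`` on the corresponding set. ``rmsep``/``r2_pre``
    are ``None`` when no prediction set was supplied.
    """

    analyte: str
    method: str
    n_factors: int
    rmsec: float
    r2_cal: float
    rmsecv: float
    r2_cv: float
    rmsep: float | None
    r2_pre: float | None


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def evaluate(
    spectra: SpectraSet,
    references: ReferenceSet,
    analyte: str,
    split: SplitResult,
    method: str = "RAW",
    mask: np.ndarray | None = None,
    n_factors: int | None = None,
    a_max: int = 10,
) -> tuple[ModelMetrics, PLSModel, CVCurve]:
    """Full evaluation protocol for one analyte and one preprocessing method.

    Preprocessing statistics are learned on the calibration samples and
    frozen for the prediction set; the factor count comes from LOO PRESS
    unless given. Returns the metrics row plus the fitted model and PRESS
    curve.
    """
    from .preprocess import Preprocessor

    cal_idx = split.calibration_sorted()
    pred_idx = split.prediction_sorted()
    if split.n_samples != spectra.n_samples:
        raise ValueError("split does not cover the dataset")
    y = references.column(analyte)
    pp = Preprocessor(method)
    cal = pp.fit_transform(spectra.subset(cal_idx))
    x_cal = cal.absorbance if mask is None else cal.absorbance[:, mask]
    y_cal = y[cal_idx]
    curve = loo_press(x_cal, y_cal, a_max=a_max)
    a = n_factors if n_factors is not None else curve.selected
    model = fit_pls(cal.absorbance, y_cal, a, mask=mask, analyte=analyte)
    yhat_cal = predict(model, cal.absorbance)
    ss_tot_cal = float(((y_cal - y_cal.mean()) ** 2).sum())
    rmsecv = float(np.sqrt(curve.press[a - 1] / len(y_cal)))
    r2_cv = 1.0 - float(curve.press[a - 1]) / ss_tot_cal
    if pred_idx.size:
        pred = pp.transform(spectra.subset(pred_idx))
        yhat_pred = predict(model, pred.absorbance)
        y_pred = y[pred_idx]
        rmsep, r2_pre = _rmse(y_pred, yhat_pred), _r2(y_pred, yhat_pred)
    else:
        rmsep, r2_pre = None, None
    metrics = ModelMetrics(
        analyte=analyte,
        method=pp.name,
        n_factors=a,
        rmsec=_rmse(y_cal, yhat_cal),
        r2_cal=_r2(y_cal, yhat_cal),
        rmsecv=rmsecv,
        r2_cv=r2_cv,
        rmsep=rmsep,
        r2_pre=r2_pre,
    )
    return metrics, model, curve
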