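"""Bootstrap-aggregated (bagging) PLS ensembles.

Each of B members is a NIPALS PLS1 model fit on a bootstrap resample (size
N, with replacement) of the calibration set, optionally restricted to a
variable mask from interval selection. Predictions aggregate by the
unweighted mean of the members (median available). The master seed spawns
per-member seeds deterministically, so the first ``b`` members — and hence
the RMSEP-versus-iterations convergence curve — are stable when B changes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import SpectraSet
from .pls import PLSModel, fit_pls, predict

__all__ = ["BaggingEnsemble", "fit_bagging", "predict_bagging", "rmsep_curve",
           "oob_rmse"]

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass
class BaggingEnsemble:
    """B bootstrap-fitted PLS members plus their resampling bookkeeping."""

    members: list[PLSModel]
    bootstrap_indices: list[np.ndarray]
    n_factors: int
    mask: np.ndarray | None
    seed: int
    aggregation: str = "mean"
    redraw_count: int = 0

    @property
    def n_members(self) -> int:
        return len(self.members)


def fit_bagging(
    x_cal: np.ndarray | SpectraSet,
    y_cal: np.ndarray,
    n_members: int = 500,
    n_factors: int = 5,
    mask: np.ndarray | None = None,
    seed: int | None = None,
    aggregation: str = "mean",
) -> BaggingEnsemble:
    """Fit a bagging-PLS ensemble.

    The factor count is fixed across members (typically the PRESS-selected A
    of the base model on the full calibration set), isolating the resampling
    effect. Degenerate resamples — zero response variance or rank below the
    requested factor count — are redrawn, with the count logged.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    xm = x_cal.absorbance if isinstance(x_cal, SpectraSet) else np.asarray(x_cal, float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n = y.size
    members: list[PLSModel] = []
    draws: list[np.ndarray] = []
    redraws = 0
    for child in np.random.SeedSequence(seed).spawn(n_members):
        rng = np.random.default_rng(child)
        for _ in range(_MAX_REDRAWS):
            idx = rng.integers(0, n, size=n)
            if np.ptp(y[idx]) == 0:
                redraws += 1
                continue
            try:
                model = fit_pls(
                    xm[idx], y[idx], n_factors, mask=mask,
                    keep_components=False,
                )
            except ValueError:
                redraws += 1
                continue
            members.append(model)
            draws.append(idx)
            break
        else:
            raise ValueError(
                f"could not draw a non-degenerate bootstrap sample in "
                f"{_MAX_REDRAWS} attempts"
            )
    if redraws:
        logger.info("redrew %d degenerate bootstrap samples", redraws)
    return BaggingEnsemble(
        members=members,
        bootstrap_indices=draws,
        n_factors=n_factors,
        mask=mask,
        seed=seed,
        aggregation=aggregation,
        redraw_count=redraws,
    )


def _member_predictions(
    ensemble: BaggingEnsemble, x: np.ndarray | SpectraSet, first_b: int | None
) -> np.ndarray:
    b = ensemble.n_members if first_b is None else int(first_b)
    if not 1 <= b <= ensemble.n_members:
        raise ValueError(f"first_b must be in [1, {ensemble.n_members}]")
    return np.vstack([predict(m, x) for m in ensemble.members[:b]])


def predict_bagging(
    ensemble: BaggingEnsemble,
    x: np.ndarray | SpectraSet,
    first_b: int | None = None,
) -> np.ndarray:
    """Aggregated prediction of the first ``first_b`` members (default all)."""
    preds = _member_predictions(ensemble, x, first_b)
    if ensemble.aggregation == "median":
        return np.median(preds, axis=0)
    return preds.mean(axis=0)


def rmsep_curve(
    ensemble: BaggingEnsemble, x_test: np.ndarray | SpectraSet, y_test: np.ndarray
) -> np.ndarray:
    """RMSEP of the prefix ensemble for every b = 1..B (convergence curve)."""
    y = np.asarray(y_test, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("test set is empty")
    preds = _member_predictions(ensemble, x_test, None)  # (B, n_test)
    if ensemble.aggregation == "median":
        agg = np.vstack(
            [np.median(preds[: b + 1], axis=0) for b in range(preds.shape[0])]
        )
    else:
        agg = np.cumsum(preds, axis=0) / np.arange(1, preds.shape[0] + 1)[:, None]
    return np.sqrt(np.mean((agg - y) ** 2, axis=1))


def oob_rmse(ensemble: BaggingEnsemble, x_cal, y_cal) -> float:
    """Out-of-bag RMSE: each calibration sample predicted by the members
    whose bootstrap draw excluded it (reported for diagnostics only)."""
    xm = x_cal.absorbance if isinstance(x_cal, SpectraSet) else np.asarray(x_cal, float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n = y.size
    sums = np.zeros(n)
    counts = np.zeros(n)
    for model, idx in zip(ensemble.members, ensemble.bootstrap_indices):
        out = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if out.size == 0:
            continue
        sums[out] += predict(model, xm[out])
        counts[out] += 1
    covered = counts > 0
    resid = y[covered] - sums[covered] / counts[covered]
    return float(np.sqrt(np.mean(resid**2)))
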