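"""Latent-variable calibration with leave-one-out cross-validation.

For each component the preprocessed spectra form an ``n x p`` matrix X
(samples x wavelengths) and the reference concentrations a vector y (mg/g).
Both are mean centered -- each wavelength's across-sample mean subtracted --
and a latent-variable regression (PLS1 by default, PCR as an alternative) is
fitted. Because only ten samples are available, model quality is judged by
leave-one-out cross-validation: each sample in turn is held out, the model
(including the centering statistics) is refitted on the rest and the held-out
concentration predicted. The figure of merit is

    RMSECV = sqrt( sum_i (yhat_i - y_i)^2 / n )

over the n held-out predictions, together with R^2 (squared Pearson
correlation of cross-validated predictions vs reference values) and the
slope/offset of the predicted-vs-reference line. The number of latent
variables is chosen by minimum RMSECV, ties broken toward fewer.

Samples whose reference concentration is an extreme outlier would distort the
calibration line, so :func:`detect_outliers` screens each component's
concentrations with a robust MAD z-score before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .concentrations import ConcentrationTable

__all__ = [
    "CalibrationModel",
    "CVResult",
    "OutlierReport",
    "PCSelection",
    "mean_center",
    "fit_model",
    "rmsecv",
    "loocv",
    "select_pcs",
    "detect_outliers",
]

logger = logging.getLogger(__name__)

Algorithm = Literal["pls1", "pcr"]


def mean_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each column's mean; returns (centered matrix, column means)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x wavelengths)")
    if X.shape[0] < 2:
        raise ValueError("centering needs at least 2 rows")
    means = X.mean(axis=0)
    return X - means, means


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted latent-variable regression for one component.

    ``coef`` and ``intercept`` express the model in the original (uncentered)
    spectral space: ``predict(x) = x @ coef + intercept``.
    """

    algorithm: str
    n_pc: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef + self.intercept


def _pls1_coef(Xc: np.ndarray, yc: np.ndarray, n_pc: int) -> np.ndarray:
    model = PLSRegression(n_components=n_pc, scale=False)
    model.fit(Xc, yc)
    return model.coef_.reshape(-1)


def _pcr_coef(Xc: np.ndarray, yc: np.ndarray, n_pc: int) -> np.ndarray:
    # principal components via thin SVD of the centered matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pc] * s[:n_pc]
    b, *_ = np.linalg.lstsq(scores, yc, rcond=None)
    return Vt[:n_pc].T @ b


def fit_model(
    X: np.ndarray,
    y: np.ndarray,
    n_pc: int,
    algorithm: Algorithm = "pls1",
) -> CalibrationModel:
    """Fit a PLS1 or PCR model with ``n_pc`` latent variables.

    Rows whose y is NaN (missing reference value) are excluded. ``n_pc = 0``
    is the null model predicting the training mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    n = y.size
    if algorithm not in ("pls1", "pcr"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if n_pc < 0 or n_pc > n - 1:
        raise ValueError(f"n_pc must be in 0..{n - 1} (got {n_pc})")
    if n_pc > 0 and np.ptp(y) == 0:
        raise ValueError("zero-variance y")
    Xc, x_mean = mean_center(X)
    y_mean = float(y.mean())
    if n_pc == 0:
        coef = np.zeros(X.shape[1])
    else:
        yc = y - y_mean
        coef = (_pls1_coef if algorithm == "pls1" else _pcr_coef)(Xc, yc, n_pc)
    return CalibrationModel(
        algorithm=algorithm, n_pc=n_pc, coef=coef, x_mean=x_mean, y_mean=y_mean
    )


def rmsecv(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error of cross-validation, sqrt(sum (yhat-y)^2 / n)."""
    y = np.asarray(y, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y.size != y_pred.size:
        raise ValueError("length mismatch between y and predictions")
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y_pred - y) ** 2)))


@dataclass(frozen=True)
class CVResult:
    """Cross-validation record for one latent-variable count."""

    n_pc: int
    rmsecv: float
    r2: float
    predictions: np.ndarray
    slope: float
    offset: float


def _prediction_line(y: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """R^2, slope and offset of the least-squares line of yhat on y."""
    if np.ptp(y_pred) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0, float(np.mean(y_pred))
    r = float(np.corrcoef(y, y_pred)[0, 1])
    slope, offset = np.polyfit(y, y_pred, 1)
    return r * r, float(slope), float(offset)


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    max_pc: int | None = None,
    algorithm: Algorithm = "pls1",
) -> list[CVResult]:
    """Leave-one-out cross-validation for 1..max_pc latent variables.

    Each fold refits the model -- including the centering statistics -- on
    the n-1 remaining samples only, so no information about the held-out
    sample leaks into the fold's preprocessing. ``max_pc`` defaults to
    ``n - 2`` (one training sample is spent on the fold, one degree of
    freedom on centering) and is clipped there with a warning if larger.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 included samples")
    feasible = n - 2
    if max_pc is None:
        max_pc = feasible
    if max_pc > feasible:
        logger.warning("max_pc=%d infeasible for n=%d; clipping to %d", max_pc, n, feasible)
        max_pc = feasible
    if max_pc < 1:
        raise ValueError("max_pc must be >= 1")

    results = []
    for n_pc in range(1, max_pc + 1):
        preds = np.empty(n)
        for i in range(n):
            train = np.arange(n) != i
            model = fit_model(X[train], y[train], n_pc, algorithm=algorithm)
            preds[i] = model.predict(X[i : i + 1])[0]
        r2, slope, offset = _prediction_line(y, preds)
        results.append(
            CVResult(
                n_pc=n_pc,
                rmsecv=rmsecv(y, preds),
                r2=r2,
                predictions=preds,
                slope=slope,
                offset=offset,
            )
        )
    return results


@dataclass(frozen=True)
class PCSelection:
    """Chosen latent-variable count plus selection diagnostics."""

    n_pc: int
    result: CVResult
    monotone_decrease: bool
    rmsecv_by_pc: dict[int, float]
    variance_profile: dict[int, float] | None = None


def select_pcs(
    results: Sequence[CVResult], variance_profile: dict[int, float] | None = None
) -> PCSelection:
    """Pick the latent-variable count with minimum RMSECV (ties -> fewer PCs).

    A ``monotone_decrease`` flag marks profiles whose RMSECV still falls at
    the largest tested count, i.e. the optimum may lie beyond ``max_pc``.
    """
    if not results:
        raise ValueError("empty result list")
    ordered = sorted(results, key=lambda r: r.n_pc)
    best = min(ordered, key=lambda r: (r.rmsecv, r.n_pc))
    values = [r.rmsecv for r in ordered]
    monotone = all(b < a for a, b in zip(values, values[1:])) and len(values) > 1
    return PCSelection(
        n_pc=best.n_pc,
        result=best,
        monotone_decrease=monotone,
        rmsecv_by_pc={r.n_pc: r.rmsecv for r in ordered},
        variance_profile=variance_profile,
    )


@dataclass(frozen=True)
class OutlierReport:
    """Robust-score screening outcome for one component."""

    component: int
    flagged: tuple[str, ...]
    scores: dict[str, float]
    threshold: float


def detect_outliers(
    table: ConcentrationTable, component: int, threshold: float = 3.5
) -> OutlierReport:
    """Flag samples whose concentration is a robust-score outlier.

    The score is ``|x - median| / (1.4826 * MAD)``; samples exceeding the
    threshold (default 3.5) are flagged. Missing entries are never flagged.
    A constant column flags nothing.
    """
    series = table.component_series(component).dropna()
    if series.size < 4:
        raise ValueError(
            f"component {component}: need >= 4 non-missing values, have {series.size}"
        )
    x = series.to_numpy(dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    scores: dict[str, float] = {}
    for sid, xi in zip(series.index, x):
        dev = abs(xi - med)
        if dev == 0.0:
            scores[str(sid)] = 0.0
        elif mad == 0.0:
            scores[str(sid)] = float("inf")
        else:
            scores[str(sid)] = dev / (1.4826 * mad)
    flagged = tuple(s for s, sc in scores.items() if sc > threshold)
    return OutlierReport(
        component=int(component), flagged=flagged, scores=scores, threshold=float(threshold)
    )
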