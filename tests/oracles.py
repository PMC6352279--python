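"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (explicit
polynomial least squares, NIPALS iterations, per-fold loops) and shares no
code path with the implementation under test.
"""

from __future__ import annotations

from math import factorial

import numpy as np


def sg_weights_bruteforce(m: int, degree: int, deriv: int) -> np.ndarray:
    """Savitzky-Golay weights by explicitly solving the local LSQ system.

    Fit f(t) ~ sum_j a_j t^j on t = -m..m; the deriv-th derivative at t=0 is
    deriv! * a_deriv, a linear functional of the samples.
    """
    t = np.arange(-m, m + 1, dtype=float)
    vander = np.vander(t, degree + 1, increasing=True)
    return factorial(deriv) * np.linalg.pinv(vander)[deriv]


def onesided_deriv_bruteforce(y: np.ndarray, footprint: int, degree: int, step: float) -> np.ndarray:
    """Forward-window LSQ polynomial first derivative, evaluated per point."""
    n = y.size - footprint
    out = np.empty(n)
    t = np.arange(footprint + 1, dtype=float)
    vander = np.vander(t, degree + 1, increasing=True)
    for i in range(n):
        coef, *_ = np.linalg.lstsq(vander, y[i : i + footprint + 1], rcond=None)
        out[i] = coef[1] / step
    return out


def pls1_nipals_coef(Xc: np.ndarray, yc: np.ndarray, n_pc: int) -> np.ndarray:
    """Textbook NIPALS PLS1 regression vector for centered data."""
    X = Xc.astype(float).copy()
    y = yc.astype(float).copy()
    W, P, Q = [], [], []
    for _ in range(n_pc):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = float(t @ t)
        p = X.T @ t / tt
        q = float(y @ t) / tt
        X = X - np.outer(t, p)
        y = y - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    W = np.array(W).T
    P = np.array(P).T
    Q = np.array(Q)
    return W @ np.linalg.solve(P.T @ W, Q)


def pcr_coef_eig(Xc: np.ndarray, yc: np.ndarray, n_pc: int) -> np.ndarray:
    """PCR regression vector via eigendecomposition of the covariance."""
    cov = Xc.T @ Xc
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_pc]
    V = vecs[:, order]
    scores = Xc @ V
    b, *_ = np.linalg.lstsq(scores, yc, rcond=None)
    return V @ b


def naive_loocv_rmsecv(X: np.ndarray, y: np.ndarray, n_pc: int, algorithm: str = "pls1") -> float:
    """Leave-one-out RMSECV by n explicit refits with per-fold centering."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    preds = np.empty(n)
    coef_fn = pls1_nipals_coef if algorithm == "pls1" else pcr_coef_eig
    for i in range(n):
        mask = np.arange(n) != i
        Xt, yt = X[mask], y[mask]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        b = coef_fn(Xt - xm, yt - ym, n_pc)
        preds[i] = ym + (X[i] - xm) @ b
    return float(np.sqrt(np.mean((preds - y) ** 2)))
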