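"""Biweight midcorrelation (bicor).

bicor is a robust correlation: each variable is centered by its median,
scaled by 9 x MAD, and observations receive Tukey biweights
``w = (1 - u^2)^2`` for ``|u| < 1`` (zero outside), after which the weighted
deviations are correlated.  A side-specific cap limits the fraction of
observations that can receive zero weight (``max_p_outliers``).  Variables
with MAD = 0 fall back to the Pearson correlation for every pair they
participate in.

Two entry points:

- :func:`bicor` — exact pairwise-complete estimator for two vectors
  (medians/MADs computed on the jointly observed subset).
- :func:`bicor_matrix` — fast variable-wise estimator for a whole
  proteins x samples matrix; with missing data, each row is standardized
  on its own observed entries and missing entries contribute zero, a
  standard approximation that is exact for complete data.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["bicor", "bicor_matrix", "bicor_cross", "bicor_p"]


def _biweight_std(x: np.ndarray, max_p_outliers: float = 1.0) -> tuple[np.ndarray, bool]:
    """Standardize a complete 1-D array with Tukey biweights.

    Returns (weighted centered vector normalized to unit L2 norm, fallback flag).
    The fallback flag is set when MAD = 0 and Pearson standardization was used.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        v = x - x.mean()
        nrm = np.sqrt(np.sum(v**2))
        return (v / nrm if nrm > 0 else v), True
    u = (x - med) / (9.0 * mad)
    if max_p_outliers < 0.5:
        # cap: no more than max_p_outliers of samples per side get weight 0
        q_lo, q_hi = np.quantile(u, [max_p_outliers, 1.0 - max_p_outliers])
        if q_lo < -1.0:
            u = np.where(u < 0, u / (-q_lo), u)
        if q_hi > 1.0:
            u = np.where(u > 0, u / q_hi, u)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    v = (x - med) * w
    nrm = np.sqrt(np.sum(v**2))
    if nrm == 0:  # degenerate weighting; fall back to Pearson
        v = x - x.mean()
        nrm = np.sqrt(np.sum(v**2))
        return (v / nrm if nrm > 0 else v), True
    return v / nrm, False


def bicor(x, y, max_p_outliers: float = 1.0) -> float:
    """Biweight midcorrelation of two vectors, pairwise-complete.

    Returns NaN when fewer than 3 jointly observed pairs exist or either
    vector is constant on the shared subset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return float("nan")
    xs, fx = _biweight_std(x[mask], max_p_outliers)
    ys, fy = _biweight_std(y[mask], max_p_outliers)
    if fx or fy:  # MAD = 0 on either side: the pair falls back to Pearson
        def _pearson_std(v):
            c = v - v.mean()
            nrm = np.linalg.norm(c)
            return c / nrm if nrm > 0 else c

        xs, ys = _pearson_std(x[mask]), _pearson_std(y[mask])
    nx, ny = np.linalg.norm(xs), np.linalg.norm(ys)
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip(np.dot(xs, ys), -1.0, 1.0))


def bicor_matrix(X: np.ndarray, max_p_outliers: float = 0.05) -> np.ndarray:
    """All-pairs bicor between the rows of ``X`` (variables x observations).

    Missing entries (NaN) are allowed: each row is standardized on its own
    observed values and missing positions contribute zero to the inner
    products.  Pairs where either row has MAD = 0 use the Pearson
    correlation instead.  Rows with zero variance yield 0 off-diagonal.
    """
    V, P, fallback = _standardize_rows(X, max_p_outliers)
    R = V @ V.T
    if fallback.any():
        # pair-level Pearson fallback: any pair touching a MAD=0 row
        Rp = P[fallback] @ P.T
        R[fallback, :] = Rp
        R[:, fallback] = Rp.T
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def _standardize_rows(X: np.ndarray, max_p_outliers: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Biweight- and Pearson-standardized rows plus per-row fallback flags."""
    X = np.asarray(X, dtype=float)
    V = np.zeros_like(X)
    P = np.zeros_like(X)
    fallback = np.zeros(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        row = X[i]
        obs = np.isfinite(row)
        vals = row[obs]
        if vals.size < 2 or np.all(vals == vals[0]):
            fallback[i] = True
            continue
        v, fb = _biweight_std(vals, max_p_outliers)
        V[i, obs] = v
        fallback[i] = fb
        p = vals - vals.mean()
        nrm = np.linalg.norm(p)
        if nrm > 0:
            P[i, obs] = p / nrm
    return V, P, fallback


def bicor_cross(X: np.ndarray, Y: np.ndarray, max_p_outliers: float = 0.05) -> np.ndarray:
    """bicor between every row of ``X`` and every row of ``Y`` (shared
    observation axis); same missing-data and MAD=0 handling as
    :func:`bicor_matrix`."""
    Vx, Px, fx = _standardize_rows(X, max_p_outliers)
    Vy, Py, fy = _standardize_rows(Y, max_p_outliers)
    R = Vx @ Vy.T
    if fx.any():
        R[fx, :] = Px[fx] @ Py.T
    if fy.any():
        R[:, fy] = Px @ Py[fy].T
    np.clip(R, -1.0, 1.0, out=R)
    return R


def bicor_p(r: float, n: int) -> float:
    """Two-sided Student-t p-value for a correlation ``r`` on ``n`` samples."""
    if not np.isfinite(r) or n < 3:
        return float("nan")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))
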