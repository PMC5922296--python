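"""Shared small statistical helpers (correlation p-values, BH adjustment)."""
from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# floor for p-values so that z = Phi^-1(1 - p/2) stays finite
_P_FLOOR = 1e-300


def corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson correlations via the exact t transform.

    t = r * sqrt((n - 2) / (1 - r^2)), df = n - 2.  |r| = 1 maps to p = 0
    (floored to the smallest representable positive p).
    """
    if n <= 2:
        raise ValueError("correlation p-values require n > 2 samples")
    r = np.asarray(r, dtype=float)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df=n - 2))
    return np.clip(p, _P_FLOOR, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, preserving shape."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    q = np.full_like(flat, np.nan)
    if ok.any():
        q[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    return q.reshape(p.shape)


def rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Correlation of every row of ``x`` with every row of ``y`` (shape gx x gy).

    Both matrices must share the sample axis (columns).  Rows with zero
    variance produce NaN entries, which callers must handle explicitly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1, keepdims=True))
    ys = np.sqrt((yc**2).sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / (xs @ ys.T)
    return np.clip(r, -1.0, 1.0)
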