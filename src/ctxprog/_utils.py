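"""Small shared numerical helpers (vectorized correlations, sphere geometry)."""
from __future__ import annotations

import numpy as np


def colwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between each column of ``a`` and the matching column of ``b``.

    Columns with zero variance in either input yield NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den == 0, np.nan, r)


def cross_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full Pearson correlation matrix between columns of ``a`` and columns of ``b``.

    Returns an (a_cols, b_cols) matrix; zero-variance columns give NaN rows/cols.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("row counts differ")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt((ac**2).sum(axis=0))
    sb = np.sqrt((bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac.T @ bc) / np.outer(sa, sb)
    r[sa == 0, :] = np.nan
    r[:, sb == 0] = np.nan
    return r


def rowwise_pearson_with(a: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``a`` with the vector ``v`` (vectorized)."""
    a = np.asarray(a, float)
    v = np.asarray(v, float)
    ac = a - a.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    num = ac @ vc
    den = np.sqrt((ac**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den == 0, np.nan, r)


def great_circle_distance(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Pairwise great-circle (angular) distances, in radians, between unit vectors."""
    x = np.asarray(x, float)
    y = x if y is None else np.asarray(y, float)
    dots = np.clip(x @ y.T, -1.0, 1.0)
    return np.arccos(dots)


def zscore_columns(m: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Center and scale columns to unit standard deviation."""
    m = np.asarray(m, float)
    mc = m - m.mean(axis=0)
    sd = mc.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a zero-variance column")
    return mc / sd
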