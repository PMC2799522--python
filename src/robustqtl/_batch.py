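"""Vectorized kernels for scanning many traits against one marker at once.

These reproduce, row-wise over a (traits x strains) matrix, the scalar
operations in :mod:`robustqtl.fligner` and the Pearson machinery of the
dispersion scans.  Agreement with the scalar paths is enforced by tests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def batch_fk_two_group(values: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Two-group Fligner-Killeen statistic for every row of ``values``.

    Parameters
    ----------
    values : (T, S) matrix, one row per trait, one column per strain unit.
    mask1 : boolean (S,) — membership of the second genotype class.

    Returns
    -------
    (T,) array of d statistics (chi-square, 1 df).  Rows whose pooled
    score variance vanishes get d = 0.
    """
    values = np.asarray(values, dtype=float)
    mask1 = np.asarray(mask1, dtype=bool)
    mask0 = ~mask1
    n0, n1 = int(mask0.sum()), int(mask1.sum())
    N = n0 + n1
    if values.shape[1] != N:
        raise ValueError("mask length must equal number of columns")

    devs = np.empty_like(values)
    devs[:, mask0] = np.abs(
        values[:, mask0] - np.median(values[:, mask0], axis=1, keepdims=True)
    )
    devs[:, mask1] = np.abs(
        values[:, mask1] - np.median(values[:, mask1], axis=1, keepdims=True)
    )
    ranks = stats.rankdata(devs, axis=1)
    scores = stats.norm.ppf(0.5 + ranks / (2.0 * (N + 1.0)))

    abar = scores.mean(axis=1)
    v2 = scores.var(axis=1, ddof=1)
    m0 = scores[:, mask0].mean(axis=1)
    m1 = scores[:, mask1].mean(axis=1)
    num = n0 * (m0 - abar) ** 2 + n1 * (m1 - abar) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(v2 > 0, num / v2, 0.0)
    return d


def batch_pearson(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``values`` with the vector ``x``.

    Rows with zero variance yield r = 0 (no linear association signal).
    """
    values = np.asarray(values, dtype=float)
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    sx = np.sqrt(np.sum(xc**2))
    vc = values - values.mean(axis=1, keepdims=True)
    sv = np.sqrt(np.sum(vc**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((sv > 0) & (sx > 0), vc @ xc / (sv * sx), 0.0)
    return np.clip(r, -1.0, 1.0)


def pearson_pvalue(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided t-test p-value for a Pearson r at sample size n (df = n-2)."""
    r = np.asarray(r, dtype=float)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p
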