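"""Shared Pearson-correlation kernel with Student-t p-values.

Every correlation in the pipeline (adjacency, module membership, gene
significance, module-trait relation, gene-pair validation) goes through
this one kernel so that all stages agree to the last bit.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["corr_matrix", "corr_with_p", "corr_pvalue"]


def corr_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Column-wise Pearson correlation between ``X`` (n x p) and ``Y`` (n x q).

    Returns a (p x q) matrix; with ``Y=None`` the (p x p) autocorrelation.
    Columns must have nonzero variance (caller validates and names offenders).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Xs = Xc / np.sqrt((Xc * Xc).sum(axis=0))
    if Y is None:
        Ys = Xs
    else:
        Y = np.asarray(Y, dtype=float)
        Yc = Y - Y.mean(axis=0)
        Ys = Yc / np.sqrt((Yc * Yc).sum(axis=0))
    r = Xs.T @ Ys
    # guard fp overshoot so downstream powers/arccos-free formulas stay in range
    return np.clip(r, -1.0, 1.0)


def corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Pearson correlation from the t transform.

    t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom; |r| = 1
    maps to p = 0. Requires n >= 3.
    """
    if n < 3:
        raise ValueError(f"p-values require at least 3 samples, got n={n}")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def corr_with_p(X: np.ndarray, Y: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix plus its two-sided p-values."""
    X = np.asarray(X, dtype=float)
    r = corr_matrix(X, Y)
    return r, corr_pvalue(r, X.shape[0])
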