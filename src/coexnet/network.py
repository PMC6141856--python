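"""Soft-thresholded adjacency, topological overlap, and power selection.

The unsigned weighted network is built from s_ij = |Pearson r(x_i, x_j)|
raised elementwise to the soft-thresholding power beta, so weak
correlations are suppressed continuously rather than hard-cut. The power
is chosen as the smallest candidate whose connectivity distribution is
approximately scale-free (signed fit index R^2 above a target, 0.90 by
default).

The topological overlap measure (TOM) between genes i and j combines
their direct adjacency with the adjacency they share through common
neighbors:

    TOM_ij = (sum_{k != i,j} a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with TOM_ii = 1; 1 - TOM is the clustering dissimilarity. The neighbor
sum excludes the endpoints, equivalently the diagonal of A is treated as
zero, which is the standard topological-overlap convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import corr_matrix
from .datamodel import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "AdjacencyMatrix",
    "TOMMatrix",
    "SoftThresholdScan",
    "adjacency",
    "tom",
    "scale_free_fit",
    "pick_soft_threshold",
]


@dataclass(frozen=True)
class NetworkConfig:
    power: int | None = None  # fixed beta; None = pick automatically
    candidate_powers: tuple = tuple(range(1, 21))
    scale_free_target: float = 0.90
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        if not (0 < self.scale_free_target <= 1):
            raise ValueError("scale_free_target must be in (0, 1]")


@dataclass
class AdjacencyMatrix:
    gene_ids: list
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0,1]
    power: int

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum over u != i of a_iu (diagonal is stored as zero)."""
        return self.matrix.sum(axis=1)


@dataclass
class TOMMatrix:
    gene_ids: list
    matrix: np.ndarray  # symmetric, unit diagonal, entries in [0,1]

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.matrix


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # power, r_squared, mean_k, median_k
    selected_power: int
    target: float
    target_met: bool = field(default=True)


def _validate_gene_variance(expr: ExpressionMatrix) -> None:
    sd = expr.values.std(axis=1)
    if (sd == 0).any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance genes (correlation undefined): {bad[:10]}")


def adjacency(expr: ExpressionMatrix, power: int) -> AdjacencyMatrix:
    """Unsigned soft-thresholded adjacency a_ij = |cor(x_i, x_j)|^power."""
    if power < 1:
        raise ValueError("soft-thresholding power must be >= 1")
    _validate_gene_variance(expr)
    s = np.abs(corr_matrix(expr.values.T))  # genes are rows -> transpose
    a = s**power
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(gene_ids=expr.gene_ids, matrix=a, power=power)


def tom(adj: AdjacencyMatrix, block_size: int | None = None) -> TOMMatrix:
    """Topological overlap matrix of an adjacency.

    ``block_size`` computes the shared-neighbor product in row blocks to
    cap peak memory; the result is identical.
    """
    a = adj.matrix
    k = adj.connectivity
    n = a.shape[0]
    denom = np.minimum.outer(k, k) + 1.0 - a
    if block_size is None or block_size >= n:
        shared = a @ a
    else:
        shared = np.empty_like(a)
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            shared[start:stop] = a[start:stop] @ a
    # zero diagonal of A already drops the k=i and k=j terms from the sum
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return TOMMatrix(gene_ids=adj.gene_ids, matrix=t)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit index of a connectivity distribution.

    Genes are binned into ``n_bins`` equal-width bins of k (k <= 0
    dropped); log10 of the per-bin frequency is regressed on log10 of the
    per-bin mean connectivity over non-empty bins. Returns the regression
    R^2, negated when the slope is positive, so values near 1 indicate a
    decaying power law p(k) ~ k^-gamma.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(np.unique(k)) < 2:
        raise ValueError("connectivity values are degenerate; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins; fit undefined")
    mean_k = np.array([k[which == b].mean() for b in np.flatnonzero(nonempty)])
    freq = counts[nonempty] / counts.sum()
    fit = stats.linregress(np.log10(mean_k), np.log10(freq))
    r2 = fit.rvalue**2
    return -r2 if fit.slope > 0 else r2


def pick_soft_threshold(expr: ExpressionMatrix, config: NetworkConfig | None = None) -> SoftThresholdScan:
    """Scan candidate powers and select the soft threshold.

    Selection rule: the smallest candidate whose signed fit index reaches
    ``scale_free_target``; if none qualifies, the argmax of the index with
    a warning.
    """
    config = config or NetworkConfig()
    candidates = list(config.candidate_powers)
    if not candidates:
        raise ValueError("candidate power list is empty")
    _validate_gene_variance(expr)
    s = np.abs(corr_matrix(expr.values.T))
    np.fill_diagonal(s, 0.0)
    rows = []
    for p in candidates:
        a = s**p
        k = a.sum(axis=1)
        r2 = scale_free_fit(k, n_bins=config.n_bins)
        rows.append({"power": p, "r_squared": r2, "mean_k": k.mean(), "median_k": np.median(k)})
    table = pd.DataFrame(rows)
    qualifying = table[table["r_squared"] >= config.scale_free_target]
    if len(qualifying):
        selected = int(qualifying.iloc[0]["power"])
        met = True
    else:
        selected = int(table.loc[table["r_squared"].idxmax(), "power"])
        met = False
        warnings.warn(
            f"no candidate power reached scale-free R^2 {config.scale_free_target}; "
            f"using argmax power {selected}",
            stacklevel=2,
        )
    logger.info("soft threshold selected: power=%d (target met: %s)", selected, met)
    return SoftThresholdScan(table=table, selected_power=selected, target=config.scale_free_target, target_met=met)
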