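"""Variance filtering and sample-level clustering diagnostics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import corr_matrix
from .datamodel import ExpressionMatrix

__all__ = ["FilterReport", "Dendrogram", "variance_filter", "cluster_samples"]


@dataclass
class FilterReport:
    n_input_genes: int
    n_retained: int
    retained_gene_ids: list
    variances: pd.Series  # per input gene, ddof=1


@dataclass
class Dendrogram:
    """Average-linkage merge tree in scipy linkage form.

    ``linkage`` rows are (left, right, height, size); leaves are indices
    into ``labels``. UPGMA is monotone, so heights are non-decreasing.
    """

    linkage: np.ndarray
    labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Serialize with branch lengths equal to merge-height differences."""
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def variance_filter(expr: ExpressionMatrix, fraction: float = 0.5):
    """Keep the top ``fraction`` most variant genes.

    Ranking is by per-gene sample variance (denominator n-1), descending;
    the retained count is floor(fraction * n_genes); ties break by gene-ID
    lexicographic order so the cut is deterministic. Returns the filtered
    matrix (original row order preserved) and a :class:`FilterReport`.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    variances = expr.data.var(axis=1, ddof=1)
    n_keep = math.floor(fraction * expr.n_genes)
    ranked = sorted(expr.gene_ids, key=lambda g: (-variances[g], g))
    keep = set(ranked[:n_keep])
    retained = [g for g in expr.gene_ids if g in keep]
    report = FilterReport(
        n_input_genes=expr.n_genes,
        n_retained=n_keep,
        retained_gene_ids=retained,
        variances=variances,
    )
    return expr.subset_genes(retained), report


def _upgma(dissimilarity: np.ndarray, labels: list) -> Dendrogram:
    condensed = squareform(dissimilarity, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, labels=list(labels))


def cluster_samples(expr: ExpressionMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) tree over samples with d = 1 - Pearson r."""
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    sd = expr.values.std(axis=0)
    if (sd == 0).any():
        bad = [expr.sample_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance samples (correlation undefined): {bad}")
    r = corr_matrix(expr.values)  # samples are columns
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return _upgma(d, expr.sample_ids)
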