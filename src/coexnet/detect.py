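"""Gene dendrogram and tree-cut module detection.

Genes are clustered by average linkage on the TOM dissimilarity 1 - TOM,
and the tree is cut at a fixed fraction of its maximum merge height; every
branch below the cut with at least ``min_module_size`` leaves becomes a
module, and all remaining genes get the reserved "grey" label. Modules are
named with the conventional color vocabulary in decreasing size order
(largest = "turquoise", then "blue", ...).

This is the static branch-cut ("tree") variant of dynamic tree cut. The
hybrid variant (adaptive break-point detection with PAM-like reassignment
by eigengene correlation) is out of scope; see the methods note for what
that fidelity gap means for module counts on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .network import TOMMatrix
from .preprocess import Dendrogram, _upgma

__all__ = ["ModuleAssignment", "cluster_genes", "dynamic_tree_cut", "module_sizes", "GREY", "MODULE_COLORS"]

GREY = "grey"

# conventional WGCNA color order, largest module first
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet",
)


@dataclass
class ModuleAssignment:
    """Gene -> module color label; "grey" is reserved for unassigned genes."""

    labels: pd.Series
    min_module_size: int

    @property
    def gene_ids(self) -> list:
        return self.labels.index.tolist()

    @property
    def module_names(self) -> list:
        """Non-grey module labels in decreasing size order."""
        counts = self.labels[self.labels != GREY].value_counts()
        return sorted(counts.index, key=lambda m: (-counts[m], m))

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def genes_in(self, label: str) -> list:
        return self.labels.index[self.labels == label].tolist()


def cluster_genes(tom: TOMMatrix) -> Dendrogram:
    """UPGMA merge tree of genes on the dissimilarity 1 - TOM."""
    if len(tom.gene_ids) < 2:
        raise ValueError("need at least 2 genes to cluster")
    d = tom.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    return _upgma(d, tom.gene_ids)


def dynamic_tree_cut(
    dend: Dendrogram,
    min_module_size: int = 30,
    cut_height_fraction: float = 0.99,
) -> ModuleAssignment:
    """Cut the gene tree into modules subject to a minimum size.

    The tree is cut at ``cut_height_fraction`` times its maximum merge
    height; branches with >= ``min_module_size`` leaves become modules
    (colors by decreasing size, ties broken by smallest member id), the
    rest are grey.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if not (0 < cut_height_fraction <= 1):
        raise ValueError("cut_height_fraction must be in (0, 1]")
    cut_height = cut_height_fraction * dend.heights.max()
    flat = hierarchy.fcluster(dend.linkage, t=cut_height, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(dend.labels), name="module", dtype=object)
    branches = []
    for branch_id in np.unique(flat):
        members = [dend.labels[i] for i in np.flatnonzero(flat == branch_id)]
        if len(members) >= min_module_size:
            branches.append(members)
    branches.sort(key=lambda members: (-len(members), min(map(str, members))))
    for rank, members in enumerate(branches):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        labels.loc[members] = color
    return ModuleAssignment(labels=labels, min_module_size=min_module_size)


def module_sizes(assign: ModuleAssignment) -> pd.DataFrame:
    """Per-module sizes; grey is reported but excluded from the module count."""
    counts = assign.labels.value_counts()
    rows = [
        {"module": m, "size": int(counts[m]), "is_grey": False}
        for m in assign.module_names
    ]
    rows.append({"module": GREY, "size": int(counts.get(GREY, 0)), "is_grey": True})
    df = pd.DataFrame(rows)
    assert df["size"].sum() == len(assign.labels)
    return df
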