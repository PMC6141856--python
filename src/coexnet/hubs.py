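"""Hub-gene screening in the clinically significant module.

Module membership (MM, also called kME) is the Pearson correlation of a
gene's expression with a module eigengene. A hub gene is a member of the
screened module with |MM| strictly above ``mm_threshold`` (default 0.8)
and absolute gene-trait correlation strictly above ``gs_threshold``
(default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import corr_with_p
from .datamodel import ExpressionMatrix

__all__ = ["HubGeneReport", "module_membership", "screen_hubs"]


@dataclass
class HubGeneReport:
    module: str
    table: pd.DataFrame  # one row per screened-module gene, descending |MM|
    mm_threshold: float
    gs_threshold: float

    @property
    def hub_genes(self) -> list:
        return self.table.index[self.table["is_hub"]].tolist()

    @property
    def n_hubs(self) -> int:
        return int(self.table["is_hub"].sum())


def module_membership(expr: ExpressionMatrix, mes: pd.DataFrame):
    """MM matrix (genes x modules) with correlation-test p-values."""
    shared = [s for s in expr.sample_ids if s in set(mes.index)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for module membership")
    X = expr.data[shared].to_numpy(dtype=float).T
    if (X.std(axis=0) == 0).any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(X.std(axis=0) == 0)]
        raise ValueError(f"zero-variance genes (MM undefined): {bad[:10]}")
    M = mes.loc[shared].to_numpy(dtype=float)
    r, p = corr_with_p(X, M)
    cols = [c.removeprefix("ME") for c in mes.columns]
    mm = pd.DataFrame(r, index=expr.gene_ids, columns=cols)
    mm_p = pd.DataFrame(p, index=expr.gene_ids, columns=cols)
    return mm, mm_p


def screen_hubs(
    mm: pd.DataFrame,
    mm_p: pd.DataFrame,
    gene_trait_cor: pd.Series,
    gene_trait_p: pd.Series,
    assign,
    module: str,
    mm_threshold: float = 0.8,
    gs_threshold: float = 0.2,
) -> HubGeneReport:
    """Flag hub genes in ``module`` by strict |MM| and |GS| thresholds.

    Only genes assigned to the screened module are eligible. Output rows
    are ordered by descending |MM| with gene-ID tie-break.
    """
    for name, thr in (("mm_threshold", mm_threshold), ("gs_threshold", gs_threshold)):
        if not (0 <= thr <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if module not in set(assign.module_names):
        raise ValueError(f"unknown module label {module!r}")
    genes = assign.genes_in(module)
    table = pd.DataFrame(
        {
            "module": module,
            "mm": mm.loc[genes, module],
            "mm_p": mm_p.loc[genes, module],
            "gene_trait_cor": gene_trait_cor.loc[genes],
            "gene_trait_p": gene_trait_p.loc[genes],
        }
    )
    table["is_hub"] = (table["mm"].abs() > mm_threshold) & (
        table["gene_trait_cor"].abs() > gs_threshold
    )
    order = sorted(table.index, key=lambda g: (-abs(table.at[g, "mm"]), str(g)))
    table = table.loc[order]
    table.index.name = "gene_id"
    return HubGeneReport(
        module=module, table=table, mm_threshold=mm_threshold, gs_threshold=gs_threshold
    )
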