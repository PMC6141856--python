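"""Hypergeometric over-representation analysis over GMT gene sets.

For a query gene list (typically a module or its hub genes) and a
collection of annotated sets, the upper-tail hypergeometric probability
of the observed overlap is computed against a stated gene universe, with
Benjamini-Hochberg adjustment across all tested sets. Sets are
intersected with the universe before testing; a set with an empty
intersection is reported with overlap 0 and p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "ora"]

DEFAULT_ALPHA = 0.001  # adjusted-P significance cut-off


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # one row per set, sorted by raw p
    universe_size: int
    query_size: int
    alpha: float

    @property
    def significant_sets(self) -> list:
        return self.table.index[self.table["significant"]].tolist()


def ora(
    query,
    sets: GeneSetCollection,
    universe,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentResult:
    """Over-representation of ``query`` in each gene set.

    p = P(X >= overlap) under Hypergeometric(universe, set, query); BH
    adjustment across all tested sets; ``significant`` flags adjusted
    p < ``alpha``. Query genes outside the universe are dropped with a
    warning log.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("empty gene universe")
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query = query & universe
    if not query:
        raise ValueError("empty query gene list")

    M, N = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        members = members & universe
        n = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {
                "set": name,
                "description": sets.descriptions.get(name, ""),
                "overlap": k,
                "set_size": n,
                "universe_size": M,
                "query_size": N,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    table["p_adjusted"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["p_adjusted"] < alpha
    table = table.sort_values(["p_value", "p_adjusted"], kind="mergesort")
    return EnrichmentResult(table=table, universe_size=M, query_size=N, alpha=alpha)
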