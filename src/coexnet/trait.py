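"""Module eigengenes, module-trait relation, gene and module significance.

The module eigengene (ME) is the first principal component of a module's
standardized expression: the single profile across samples that explains
the largest share of the module's variance. Gene significance (GS)
measures a gene's association with a clinical trait either as the
absolute Pearson correlation ("correlation" mode, used for hub
screening) or as -log10 of the correlation-test p-value ("neglogp"
mode, used for the per-module significance bars); module significance
(MS) is the mean absolute GS over a module's genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import corr_pvalue, corr_with_p
from .datamodel import ExpressionMatrix, TraitTable, align_samples
from .detect import GREY, ModuleAssignment

__all__ = [
    "ModuleTraitResult",
    "module_eigengene",
    "module_eigengenes",
    "module_trait_correlation",
    "gene_significance",
    "module_significance",
    "relate_modules_to_traits",
]


def _standardized_module(expr: ExpressionMatrix, genes: list) -> np.ndarray:
    X = expr.data.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [genes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance genes in module: {bad[:10]}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def module_eigengene(expr: ExpressionMatrix, assign: ModuleAssignment, module_label: str) -> pd.Series:
    """First principal component score of a module across samples.

    Genes are standardized (mean 0, sd 1 across samples); the ME is the
    unit-normalized leading right singular vector, sign-aligned so it
    correlates non-negatively with the mean standardized module profile.
    """
    genes = assign.genes_in(module_label)
    if len(genes) < 2:
        raise ValueError(f"module {module_label!r} has fewer than 2 genes")
    X = _standardized_module(expr, genes)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    me = vt[0]
    mean_profile = X.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return pd.Series(me, index=expr.sample_ids, name=f"ME{module_label}")


def module_eigengenes(
    expr: ExpressionMatrix, assign: ModuleAssignment, include_grey: bool = False
) -> pd.DataFrame:
    """Samples x modules eigengene matrix (columns ``ME<color>``)."""
    modules = list(assign.module_names)
    if include_grey and (assign.labels == GREY).sum() >= 2:
        modules.append(GREY)
    if not modules:
        raise ValueError("assignment contains no modules")
    return pd.DataFrame({f"ME{m}": module_eigengene(expr, assign, m) for m in modules})


@dataclass
class ModuleTraitResult:
    eigengenes: pd.DataFrame  # samples x MEs
    correlation: pd.DataFrame  # modules x traits
    p_value: pd.DataFrame
    gene_trait_cor: pd.DataFrame  # genes x traits
    gene_trait_p: pd.DataFrame
    gs: pd.DataFrame  # genes x traits, per the chosen GS mode
    gs_mode: str
    ms: pd.DataFrame  # module, trait columns, grey flagged
    significant_module: dict  # trait -> module label with max |r|
    n_samples: int


def module_trait_correlation(mes: pd.DataFrame, traits: TraitTable):
    """Pearson correlation of each ME with each trait, with t-test p-values.

    Returns ``(correlation, p_value, significant_module)`` where the last
    maps each trait to the module with the largest |r|.
    """
    shared = [s for s in mes.index if s in set(traits.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for module-trait correlation")
    M = mes.loc[shared].to_numpy(dtype=float)
    T = traits.data.loc[shared].to_numpy(dtype=float)
    const = T.std(axis=0) == 0
    if const.any():
        bad = [traits.trait_names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant traits (correlation undefined): {bad}")
    r, p = corr_with_p(M, T)
    module_index = [c.removeprefix("ME") for c in mes.columns]
    cor = pd.DataFrame(r, index=module_index, columns=traits.trait_names)
    pv = pd.DataFrame(p, index=module_index, columns=traits.trait_names)
    significant = {t: cor[t].abs().idxmax() for t in cor.columns}
    return cor, pv, significant


def gene_significance(
    expr: ExpressionMatrix, trait: pd.Series, mode: str = "correlation"
) -> pd.Series:
    """Per-gene association with a trait vector.

    mode "correlation": GS_g = |Pearson r(x_g, trait)|;
    mode "neglogp":     GS_g = -log10(p_g) from the same correlation t-test.
    """
    if mode not in ("correlation", "neglogp"):
        raise ValueError(f"unknown GS mode {mode!r}")
    shared = [s for s in expr.sample_ids if s in set(trait.index)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for gene significance")
    X = expr.data[shared].to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance genes (GS undefined): {bad[:10]}")
    t = trait.loc[shared].to_numpy(dtype=float)[:, None]
    if t.std() == 0:
        raise ValueError("constant trait (GS undefined)")
    r, p = corr_with_p(X, t)
    if mode == "correlation":
        values = np.abs(r[:, 0])
    else:
        values = -np.log10(np.maximum(p[:, 0], np.finfo(float).tiny))
    return pd.Series(values, index=expr.gene_ids, name=f"GS_{mode}")


def module_significance(gs: pd.Series, assign: ModuleAssignment) -> pd.DataFrame:
    """MS_m = mean absolute gene significance over module m's genes."""
    missing = [g for g in assign.gene_ids if g not in gs.index]
    if missing:
        raise ValueError(f"GS missing for genes {missing[:5]}")
    rows = []
    for m in assign.module_names + ([GREY] if (assign.labels == GREY).any() else []):
        genes = assign.genes_in(m)
        if not genes:
            raise ValueError(f"module {m!r} is empty")
        rows.append({"module": m, "ms": float(gs.loc[genes].abs().mean()), "is_grey": m == GREY})
    return pd.DataFrame(rows)


def relate_modules_to_traits(
    expr: ExpressionMatrix,
    assign: ModuleAssignment,
    traits: TraitTable,
    ms_trait: str | None = None,
    gs_mode: str = "correlation",
) -> ModuleTraitResult:
    """Full module-trait relation: MEs, ME-trait correlations, GS and MS.

    ``ms_trait`` names the trait used for the MS table (default: first
    trait). GS tables in both modes are available; ``gs_mode`` selects
    which one feeds downstream hub screening.
    """
    expr_al, traits_al = align_samples(expr, traits)
    mes = module_eigengenes(expr_al, assign)
    cor, pv, significant = module_trait_correlation(mes, traits_al)

    X = expr_al.values.T
    T = traits_al.data.to_numpy(dtype=float)
    r, p = corr_with_p(X, T)
    gtc = pd.DataFrame(r, index=expr_al.gene_ids, columns=traits_al.trait_names)
    gtp = pd.DataFrame(p, index=expr_al.gene_ids, columns=traits_al.trait_names)
    if gs_mode == "correlation":
        gs = gtc.abs()
    else:
        gs = -np.log10(np.maximum(gtp, np.finfo(float).tiny))

    ms_trait = ms_trait or traits_al.trait_names[0]
    ms = module_significance(gs[ms_trait], assign)
    return ModuleTraitResult(
        eigengenes=mes,
        correlation=cor,
        p_value=pv,
        gene_trait_cor=gtc,
        gene_trait_p=gtp,
        gs=gs,
        gs_mode=gs_mode,
        ms=ms,
        significant_module=significant,
        n_samples=len(expr_al.sample_ids),
    )
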