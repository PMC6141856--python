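"""Model/Results surface tying the pipeline stages together.

``WGCNA`` is constructed from an expression matrix (and optionally a
trait table); ``fit()`` runs variance filtering, soft-threshold
selection, adjacency and TOM construction, gene clustering, tree-cut
module detection, module-trait relation and hub screening, and returns a
:class:`WGCNAResults` carrying every intermediate artifact plus a
``summary()`` table.

Typical use::

    from coexnet import WGCNA
    res = WGCNA(expr, traits, primary_trait="grade").fit()
    print(res.summary())
    res.hub_report.hub_genes
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import detect, hubs, network, preprocess, trait
from .datamodel import ExpressionMatrix, TraitTable

logger = logging.getLogger(__name__)

__all__ = ["WGCNA", "WGCNAResults"]


class WGCNA:
    """Weighted gene co-expression network analysis model.

    Parameters
    ----------
    expression
        Genes x samples log-scale expression matrix.
    traits
        Optional samples x traits table; required for the module-trait
        relation and hub screening stages.
    variance_fraction
        Fraction of most-variant genes retained before network
        construction (None disables filtering).
    power
        Soft-thresholding power beta; None selects the smallest candidate
        reaching ``scale_free_target``.
    min_module_size, cut_height_fraction
        Tree-cut parameters for module detection.
    primary_trait
        Trait used to pick the clinically significant module and to
        screen hubs (default: first trait column).
    mm_threshold, gs_threshold
        Strict hub-screening cut-offs on |module membership| and
        |gene-trait correlation|.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        traits: TraitTable | None = None,
        *,
        variance_fraction: float | None = 0.5,
        power: int | None = None,
        candidate_powers=tuple(range(1, 21)),
        scale_free_target: float = 0.90,
        n_bins: int = 10,
        min_module_size: int = 30,
        cut_height_fraction: float = 0.99,
        primary_trait: str | None = None,
        mm_threshold: float = 0.8,
        gs_threshold: float = 0.2,
        tom_block_size: int | None = None,
    ):
        self.expression = expression
        self.traits = traits
        self.variance_fraction = variance_fraction
        self.network_config = network.NetworkConfig(
            power=power,
            candidate_powers=tuple(candidate_powers),
            scale_free_target=scale_free_target,
            n_bins=n_bins,
        )
        self.min_module_size = min_module_size
        self.cut_height_fraction = cut_height_fraction
        self.primary_trait = primary_trait
        self.mm_threshold = mm_threshold
        self.gs_threshold = gs_threshold
        self.tom_block_size = tom_block_size

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        traits: pd.DataFrame | None = None,
        orientation: str = "genes-in-rows",
        **kwargs,
    ) -> "WGCNA":
        """Build the model from plain DataFrames."""
        if orientation == "samples-in-rows":
            expression = expression.T
        expr = ExpressionMatrix(expression.astype(float))
        tt = TraitTable(traits.astype(float)) if traits is not None else None
        return cls(expr, tt, **kwargs)

    def fit(self) -> "WGCNAResults":
        expr = self.expression
        filter_report = None
        if self.variance_fraction is not None:
            expr, filter_report = preprocess.variance_filter(expr, self.variance_fraction)
            logger.info(
                "variance filter: %d -> %d genes", filter_report.n_input_genes, filter_report.n_retained
            )

        scan = None
        power = self.network_config.power
        if power is None:
            scan = network.pick_soft_threshold(expr, self.network_config)
            power = scan.selected_power
        adj = network.adjacency(expr, power)
        tom_matrix = network.tom(adj, block_size=self.tom_block_size)
        dendrogram = detect.cluster_genes(tom_matrix)
        assignment = detect.dynamic_tree_cut(
            dendrogram,
            min_module_size=self.min_module_size,
            cut_height_fraction=self.cut_height_fraction,
        )
        logger.info("detected %d modules (+%d grey genes)",
                    assignment.n_modules, int((assignment.labels == detect.GREY).sum()))

        module_trait = None
        hub_report = None
        mm = mm_p = None
        if self.traits is not None and assignment.n_modules:
            module_trait = trait.relate_modules_to_traits(
                expr, assignment, self.traits, ms_trait=self.primary_trait, gs_mode="correlation"
            )
            mm, mm_p = hubs.module_membership(expr, module_trait.eigengenes)
            key_trait = self.primary_trait or self.traits.trait_names[0]
            significant = module_trait.significant_module[key_trait]
            hub_report = hubs.screen_hubs(
                mm,
                mm_p,
                module_trait.gene_trait_cor[key_trait],
                module_trait.gene_trait_p[key_trait],
                assignment,
                significant,
                mm_threshold=self.mm_threshold,
                gs_threshold=self.gs_threshold,
            )
        return WGCNAResults(
            model=self,
            expression=expr,
            filter_report=filter_report,
            power=power,
            power_scan=scan,
            adjacency=adj,
            tom=tom_matrix,
            gene_dendrogram=dendrogram,
            modules=assignment,
            module_trait=module_trait,
            module_membership=mm,
            module_membership_p=mm_p,
            hub_report=hub_report,
        )


@dataclass
class WGCNAResults:
    """Fitted-analysis artifacts with summary and plotting helpers."""

    model: WGCNA
    expression: ExpressionMatrix  # post-filter matrix the network was built on
    filter_report: preprocess.FilterReport | None
    power: int
    power_scan: network.SoftThresholdScan | None
    adjacency: network.AdjacencyMatrix
    tom: network.TOMMatrix
    gene_dendrogram: preprocess.Dendrogram
    modules: detect.ModuleAssignment
    module_trait: trait.ModuleTraitResult | None
    module_membership: pd.DataFrame | None
    module_membership_p: pd.DataFrame | None
    hub_report: hubs.HubGeneReport | None
    extras: dict = field(default_factory=dict)

    @property
    def significant_module(self) -> str | None:
        if self.module_trait is None:
            return None
        key = self.model.primary_trait or self.model.traits.trait_names[0]
        return self.module_trait.significant_module[key]

    def summary(self) -> str:
        lines = ["Weighted co-expression network analysis", "=" * 40]
        if self.filter_report is not None:
            lines.append(
                f"Genes: {self.filter_report.n_input_genes} input, "
                f"{self.filter_report.n_retained} retained by variance filter"
            )
        else:
            lines.append(f"Genes: {self.expression.n_genes} (no variance filter)")
        lines.append(f"Samples: {self.expression.n_samples}")
        if self.power_scan is not None:
            row = self.power_scan.table.set_index("power").loc[self.power]
            lines.append(
                f"Soft threshold: beta = {self.power} "
                f"(scale-free R^2 = {row['r_squared']:.3f}, mean k = {row['mean_k']:.2f})"
            )
        else:
            lines.append(f"Soft threshold: beta = {self.power} (fixed)")
        sizes = detect.module_sizes(self.modules)
        n_grey = int(sizes.loc[sizes["is_grey"], "size"].sum())
        lines.append(f"Modules: {self.modules.n_modules} (grey/unassigned genes: {n_grey})")
        for _, r in sizes[~sizes["is_grey"]].iterrows():
            lines.append(f"  {r['module']:<14s} {r['size']:>6d} genes")
        if self.module_trait is not None:
            key = self.model.primary_trait or self.model.traits.trait_names[0]
            mod = self.significant_module
            r = self.module_trait.correlation.at[mod, key]
            p = self.module_trait.p_value.at[mod, key]
            lines.append(
                f"Clinically significant module for {key!r}: {mod} "
                f"(ME-trait r = {r:.3f}, p = {p:.3g})"
            )
        if self.hub_report is not None:
            lines.append(
                f"Hub genes in {self.hub_report.module} "
                f"(|MM| > {self.hub_report.mm_threshold}, |GS| > {self.hub_report.gs_threshold}): "
                f"{self.hub_report.n_hubs}"
            )
        return "\n".join(lines)

    # -- plotting (thin matplotlib wrappers; not part of the numeric surface)

    def plot_soft_threshold(self, ax=None):
        import matplotlib.pyplot as plt

        if self.power_scan is None:
            raise ValueError("no power scan available (fixed power)")
        if ax is None:
            _, ax = plt.subplots()
        t = self.power_scan.table
        ax.plot(t["power"], t["r_squared"], "o-")
        ax.axhline(self.power_scan.target, ls="--", c="r")
        ax.set_xlabel("soft-thresholding power")
        ax.set_ylabel("signed scale-free fit $R^2$")
        return ax

    def plot_gene_dendrogram(self, ax=None):
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy

        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(self.gene_dendrogram.linkage, no_labels=True, ax=ax)
        ax.set_ylabel("1 - TOM")
        return ax

    def plot_module_trait_heatmap(self, ax=None):
        import matplotlib.pyplot as plt

        if self.module_trait is None:
            raise ValueError("no trait table was supplied")
        if ax is None:
            _, ax = plt.subplots()
        cor = self.module_trait.correlation
        im = ax.imshow(cor.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(cor.shape[1]), cor.columns)
        ax.set_yticks(range(cor.shape[0]), cor.index)
        plt.colorbar(im, ax=ax, label="ME-trait Pearson r")
        return ax
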