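"""End-to-end pipeline orchestration with one config, one seed.

Stages: simulate (optional) -> filter -> network -> modules -> relate ->
hubs -> validate -> enrich. Every stage writes its tables (TSV / JSON /
Newick) under the output directory; the run summary JSON records module
count, the significant module, hub count, per-hub validation statistics
and a sha256 checksum per output file. A stage failure aborts with the
stage name and cause; partial outputs are kept next to a FAILED marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import detect, enrich as enrich_mod, validate as validate_mod
from .datamodel import (
    SurvivalTable,
    read_expression,
    read_gmt,
    read_survival,
    read_traits,
    write_expression,
    write_survival,
    write_traits,
)
from .model import WGCNA
from .simulate import SimulationConfig, simulate_expression, simulate_survival, simulate_tumor_labels

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "default_config", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    output_dir: str = "coexnet_run"
    seed: int = 7
    log_level: str = "INFO"
    # input paths; None + simulate=True generates them
    simulate: bool = True
    expression_path: str | None = None
    trait_path: str | None = None
    survival_path: str | None = None
    gmt_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # analysis parameters
    variance_fraction: float = 0.5
    power: int | None = 9  # the study's soft threshold; None = scale-free auto-selection
    scale_free_target: float = 0.90
    n_bins: int = 10
    min_module_size: int = 30
    cut_height_fraction: float = 0.99
    primary_trait: str | None = None
    mm_threshold: float = 0.8
    gs_threshold: float = 0.2

    def __post_init__(self) -> None:
        for name in ("mm_threshold", "gs_threshold"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim:
            sim = {**dataclasses.asdict(cfg.simulation), **sim}
            for key in ("module_sizes", "module_loading_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["simulation"] = dataclasses.asdict(self.simulation)
        for key in ("module_sizes", "module_loading_range"):
            raw["simulation"][key] = list(raw["simulation"][key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_config(**overrides) -> PipelineConfig:
    return PipelineConfig(**overrides)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run the full workflow; returns (and writes) the run summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise StageError(name, exc) from exc
            summary["stages"][name] = {"elapsed_s": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrap

    # ---- inputs (simulated or loaded) ------------------------------------
    truth = None
    if config.simulate:
        def _simulate():
            expr, traits, tr = simulate_expression(config.simulation)
            surv = simulate_survival(expr, tr, config.simulation)
            expr_shifted, tumor = simulate_tumor_labels(expr, tr, config.simulation)
            emit("expression.tsv", lambda p: write_expression(expr, p))
            emit("traits.tsv", lambda p: write_traits(traits, p))
            emit("survival.tsv", lambda p: write_survival(surv, p))
            emit("tumor_labels.tsv", lambda p: write_traits(tumor, p))
            emit("expression_tumor_shifted.tsv", lambda p: write_expression(expr_shifted, p))
            emit("truth.json", lambda p: p.write_text(json.dumps({
                "module_labels": tr.module_labels.to_dict(),
                "loadings": tr.loadings.to_dict(),
                "trait_module": tr.trait_module,
                "survival_gene": tr.survival_gene,
                "shifted_genes": tr.shifted_genes,
            }, indent=1)))
            return expr, traits, surv, tumor, expr_shifted, tr

        expr, traits, surv, tumor, expr_shifted, truth = stage("simulate")(_simulate)
        gene_sets = None if config.gmt_path is None else read_gmt(config.gmt_path)
    else:
        def _load():
            if config.expression_path is None:
                raise ValueError("expression_path is required when simulate is false")
            expr = read_expression(config.expression_path)
            traits = read_traits(config.trait_path) if config.trait_path else None
            surv = read_survival(config.survival_path) if config.survival_path else None
            gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None
            return expr, traits, surv, gene_sets

        expr, traits, surv, gene_sets = stage("load")(_load)
        tumor = expr_shifted = None

    # ---- network model (filter / network / modules / relate / hubs) ------
    def _fit():
        if traits is None:
            raise ValueError(
                "module-trait relation needs a trait table; supply trait_path or enable simulate"
            )
        model = WGCNA(
            expr,
            traits,
            variance_fraction=config.variance_fraction,
            power=config.power,
            scale_free_target=config.scale_free_target,
            n_bins=config.n_bins,
            min_module_size=config.min_module_size,
            cut_height_fraction=config.cut_height_fraction,
            primary_trait=config.primary_trait,
            mm_threshold=config.mm_threshold,
            gs_threshold=config.gs_threshold,
        )
        return model.fit()

    res = stage("fit")(_fit)

    def _write_fit():
        emit("module_assignment.tsv",
             lambda p: res.modules.labels.rename("module").to_csv(p, sep="\t", index_label="gene_id"))
        emit("gene_dendrogram.nwk", lambda p: p.write_text(res.gene_dendrogram.to_newick() + "\n"))
        if res.power_scan is not None:
            emit("soft_threshold_scan.tsv",
                 lambda p: res.power_scan.table.to_csv(p, sep="\t", index=False))
        mt = res.module_trait
        emit("module_eigengenes.tsv", lambda p: mt.eigengenes.to_csv(p, sep="\t", index_label="sample_id"))
        emit("module_trait_correlation.tsv", lambda p: mt.correlation.to_csv(p, sep="\t", index_label="module"))
        emit("module_trait_pvalue.tsv", lambda p: mt.p_value.to_csv(p, sep="\t", index_label="module"))
        emit("gene_significance.tsv", lambda p: mt.gs.to_csv(p, sep="\t", index_label="gene_id"))
        emit("module_significance.tsv", lambda p: mt.ms.to_csv(p, sep="\t", index=False))
        emit("hub_genes.tsv", lambda p: res.hub_report.table.to_csv(p, sep="\t"))
        emit("summary.txt", lambda p: p.write_text(res.summary() + "\n"))

    stage("write_fit")(_write_fit)

    # ---- validation -------------------------------------------------------
    validation_rows = []
    if surv is not None and res.hub_report is not None:
        def _validate():
            hub_genes = res.hub_report.hub_genes
            vexpr = expr_shifted if expr_shifted is not None else expr
            for gene in hub_genes:
                row = {"gene_id": gene}
                values = res.expression.data.loc[gene]
                shared = [s for s in values.index if s in set(surv.sample_ids)]
                groups = validate_mod.median_split(values.loc[shared])
                surv_shared = SurvivalTable(surv.data.loc[shared])
                lr = validate_mod.logrank_test(surv_shared, groups)
                row["logrank_chi2"] = lr.statistic
                row["logrank_p"] = lr.p_value
                if tumor is not None:
                    lbl = tumor.data["tumor"]
                    shared_t = [s for s in vexpr.sample_ids if s in set(lbl.index)]
                    roc = validate_mod.roc_auc(
                        vexpr.data.loc[gene, shared_t].to_numpy(),
                        lbl.loc[shared_t].to_numpy(),
                    )
                    t, df, p = validate_mod.two_group_ttest(
                        vexpr.data.loc[gene, shared_t].to_numpy(), lbl.loc[shared_t].to_numpy()
                    )
                    row.update({"auc": roc.auc, "ttest_t": t, "ttest_p": p})
                validation_rows.append(row)
            if validation_rows:
                import pandas as pd

                emit("hub_validation.tsv",
                     lambda p: pd.DataFrame(validation_rows).to_csv(p, sep="\t", index=False))

        stage("validate")(_validate)

    # ---- enrichment -------------------------------------------------------
    if gene_sets is not None and res.hub_report is not None and res.hub_report.hub_genes:
        def _enrich():
            result = enrich_mod.ora(
                res.hub_report.hub_genes, gene_sets, res.expression.gene_ids
            )
            emit("enrichment.tsv", lambda p: result.table.to_csv(p, sep="\t"))
            return result

        stage("enrich")(_enrich)

    # ---- summary ----------------------------------------------------------
    sizes = detect.module_sizes(res.modules)
    summary.update(
        {
            "n_genes_input": expr.n_genes,
            "n_genes_retained": res.expression.n_genes,
            "power": res.power,
            "n_modules": res.modules.n_modules,
            "module_sizes": {r["module"]: int(r["size"]) for _, r in sizes.iterrows()},
            "significant_module": res.significant_module,
            "n_hubs": res.hub_report.n_hubs if res.hub_report else None,
            "hub_validation": validation_rows,
        }
    )
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        planted = truth.module_labels.loc[res.modules.gene_ids]
        summary["module_recovery_ari"] = float(
            adjusted_rand_score(planted.to_numpy(), res.modules.labels.to_numpy())
        )
    summary["outputs"] = {p.name: _sha256(p) for p in written}
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
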