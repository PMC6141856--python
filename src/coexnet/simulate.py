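"""Synthetic expression / trait / survival / tumor-label generator.

The generator emulates the statistical structure the network analysis
assumes: a ~49-sample microarray-scale matrix containing latent-factor
driven co-expression modules, one of which is coupled to an ordinal tumor
grade (1-3), a background of low-variance noise genes, expression-dependent
exponential survival times, and tumor-vs-normal mean shifts on designated
genes.

Each planted module m has a latent eigengene e_m (standardized across
samples); a gene g planted in m is

    x_g = loading_g * e_m + eps,   eps ~ Normal(0, noise_sd^2)

with loadings drawn uniformly from ``module_loading_range``. Background
genes are pure Normal(0, noise_sd^2) noise, so their total variance sits
below every module gene's (loading^2 + noise_sd^2) and a top-variance
filter preferentially retains planted signal, as it does on real arrays.

All randomness flows from the single ``seed`` through named
``numpy.random.Generator`` streams; no global RNG state is touched.
Identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import ExpressionMatrix, SurvivalTable, TraitTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_survival",
    "simulate_tumor_labels",
]

UNASSIGNED = "unassigned"

# stream offsets so the three operations draw from independent, seeded streams
_EXPR_STREAM, _SURV_STREAM, _TUMOR_STREAM = 11, 23, 37


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror a 49-sample breast-tumor array cohort with four planted
    modules (100/80/60/40 genes), 300 background genes, and the second
    largest module driving tumor grade (so its detected color label is
    "blue" under size-ordered coloring).
    """

    n_samples: int = 49
    n_background_genes: int = 300
    module_sizes: tuple = (100, 80, 60, 40)
    module_loading_range: tuple = (0.6, 0.95)
    noise_sd: float = 0.6
    trait_module_index: int = 1
    trait_effect: float = 2.0
    trait_noise_sd: float = 1.0
    survival_gene: str | None = None  # default: highest-loading trait-module gene
    baseline_hazard: float = 0.1
    survival_log_hazard_coef: float = 1.0
    censoring_fraction: float = 0.3
    tumor_fraction: float = 0.5
    tumor_shift: float = 2.0
    seed: int = 7

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if not (0 < self.module_loading_range[0] <= self.module_loading_range[1] < 1):
            raise ValueError("module_loading_range must be an interval within (0,1)")
        for name in ("noise_sd", "trait_noise_sd", "baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0,1)")
        if sum(self.module_sizes) + self.n_background_genes == 0:
            raise ValueError("no genes to simulate")
        if self.module_sizes and not (0 <= self.trait_module_index < len(self.module_sizes)):
            raise ValueError("trait_module_index out of range")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    module_labels: pd.Series  # gene -> "M1".. / "unassigned"
    eigengenes: pd.DataFrame  # modules x samples, standardized rows
    loadings: pd.Series  # gene -> loading (0 for background)
    trait: pd.Series  # sample -> grade 1..3
    trait_module: str
    survival_gene: str | None = None
    shifted_genes: dict = field(default_factory=dict)  # gene -> mean shift

    def genes_in_module(self, label: str) -> list:
        return self.module_labels.index[self.module_labels == label].tolist()


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    return X / X.std(axis=1, keepdims=True)


def simulate_expression(config: SimulationConfig):
    """Draw the expression matrix, the grade trait and the planted truth.

    Returns ``(ExpressionMatrix, TraitTable, SyntheticTruth)``.
    """
    rng = np.random.default_rng([_EXPR_STREAM, config.seed])
    n = config.n_samples
    m = len(config.module_sizes)
    n_genes = sum(config.module_sizes) + config.n_background_genes

    E = _standardize_rows(rng.standard_normal((m, n))) if m else np.empty((0, n))
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    lo, hi = config.module_loading_range
    values = np.empty((n_genes, n))
    labels = np.empty(n_genes, dtype=object)
    loadings = np.zeros(n_genes)
    row = 0
    for j, size in enumerate(config.module_sizes):
        load = rng.uniform(lo, hi, size=size)
        noise = rng.normal(0.0, config.noise_sd, size=(size, n))
        values[row : row + size] = load[:, None] * E[j] + noise
        labels[row : row + size] = f"M{j + 1}"
        loadings[row : row + size] = load
        row += size
    if config.n_background_genes:
        values[row:] = rng.normal(0.0, config.noise_sd, size=(config.n_background_genes, n))
        labels[row:] = UNASSIGNED

    if m:
        e_trait = E[config.trait_module_index]
        raw = config.trait_effect * e_trait + rng.normal(0.0, config.trait_noise_sd, size=n)
    else:
        raw = rng.normal(0.0, 1.0, size=n)
    cuts = np.quantile(raw, [1 / 3, 2 / 3])
    grade = np.digitize(raw, cuts) + 1  # ordinal 1..3, monotone in raw

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    traits = TraitTable(
        pd.DataFrame({"grade": grade.astype(float)}, index=sample_ids),
        encoding_notes={"grade": "ordinal tumor grade 1-3"},
    )
    trait_module = f"M{config.trait_module_index + 1}" if m else UNASSIGNED
    truth = SyntheticTruth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        eigengenes=pd.DataFrame(E, index=[f"M{j + 1}" for j in range(m)], columns=sample_ids),
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        trait=pd.Series(grade, index=sample_ids, name="grade"),
        trait_module=trait_module,
        survival_gene=_default_survival_gene(config, labels, loadings, gene_ids),
    )
    return expr, traits, truth


def _default_survival_gene(config, labels, loadings, gene_ids):
    if config.survival_gene is not None:
        return config.survival_gene
    if not len(config.module_sizes):
        return gene_ids[0] if gene_ids else None
    trait_label = f"M{config.trait_module_index + 1}"
    mask = labels == trait_label
    idx = np.flatnonzero(mask)
    return gene_ids[idx[np.argmax(loadings[idx])]]


def simulate_survival(
    expr: ExpressionMatrix, truth: SyntheticTruth, config: SimulationConfig
) -> SurvivalTable:
    """Exponential survival times driven by one gene's expression.

    Per-sample hazard is ``baseline_hazard * exp(coef * z_s)`` where z is
    the standardized expression of ``survival_gene``. Censoring is an
    independent Uniform(0, c) competitor with c calibrated on the drawn
    event times so the expected censored fraction matches the target.
    """
    gene = config.survival_gene or truth.survival_gene
    if gene not in expr.data.index:
        raise ValueError(f"unknown survival gene {gene!r}")
    rng = np.random.default_rng([_SURV_STREAM, config.seed])
    x = expr.data.loc[gene].to_numpy(dtype=float)
    z = (x - x.mean()) / x.std()
    rate = config.baseline_hazard * np.exp(config.survival_log_hazard_coef * z)
    t_event = rng.exponential(1.0 / rate)

    if config.censoring_fraction == 0:
        time, event = t_event, np.ones_like(t_event, dtype=int)
    else:
        # with C ~ U(0,c): P(C < T) = E[min(T,c)]/c, which decreases from 1
        # (c -> 0) to 0 (c -> inf); calibrate c on the drawn event times
        def censored_frac(c):
            return np.minimum(t_event, c).mean() / c

        target = config.censoring_fraction
        c_hi = t_event.max() * 2.0
        while censored_frac(c_hi) > target:
            c_hi *= 2.0
        c_max = brentq(lambda c: censored_frac(c) - target, t_event.min() * 1e-9, c_hi)
        t_cens = rng.uniform(0.0, c_max, size=len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    return SurvivalTable(
        pd.DataFrame({"time": time, "event": event}, index=expr.sample_ids)
    )


def simulate_tumor_labels(
    expr: ExpressionMatrix,
    truth: SyntheticTruth,
    config: SimulationConfig,
    shifted_genes: list | None = None,
):
    """Assign tumor/normal labels and add mean shifts to designated genes.

    Exactly ``round(tumor_fraction * n_samples)`` samples become tumors.
    The designated genes (default: the trait module's planted genes) get
    ``tumor_shift`` added in tumor samples; shifts are recorded in
    ``truth.shifted_genes``. Returns ``(shifted ExpressionMatrix,
    TraitTable with binary 'tumor' trait)``.
    """
    rng = np.random.default_rng([_TUMOR_STREAM, config.seed])
    n = expr.n_samples
    n_tumor = int(round(config.tumor_fraction * n))
    order = rng.permutation(n)
    is_tumor = np.zeros(n, dtype=int)
    is_tumor[order[:n_tumor]] = 1

    if shifted_genes is None:
        shifted_genes = truth.genes_in_module(truth.trait_module)
    missing = [g for g in shifted_genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"unknown genes to shift: {missing[:5]}")

    data = expr.data.copy()
    if shifted_genes:
        data.loc[shifted_genes] = data.loc[shifted_genes].to_numpy() + np.outer(
            np.full(len(shifted_genes), config.tumor_shift), is_tumor
        )
    truth.shifted_genes = {g: config.tumor_shift for g in shifted_genes}
    labels = TraitTable(
        pd.DataFrame({"tumor": is_tumor.astype(float)}, index=expr.sample_ids),
        encoding_notes={"tumor": "binary 1=tumor 0=normal"},
    )
    return ExpressionMatrix(data), labels


def null_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of ``config`` with every planted effect switched off.

    Used for calibration checks: trait, survival and tumor-shift effects
    are zeroed so every downstream p-value should be uniform.
    """
    base = config or SimulationConfig()
    return replace(
        base,
        trait_effect=0.0,
        survival_log_hazard_coef=0.0,
        tumor_shift=0.0,
        **overrides,
    )
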