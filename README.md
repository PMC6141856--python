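# coexnet

Weighted gene co-expression network analysis (WGCNA) for bulk expression
matrices, built for finding clinically relevant gene modules and hub genes —
the kind of analysis used to screen prognosis-associated candidate biomarkers
in tumor transcriptomes (e.g. a ~6,000-gene, ~49-sample breast-cancer
microarray cohort with an ordinal tumor-grade trait).

The package covers the full workflow:

1. **Variance filter** — keep the top fraction (default 50%) most variant
   genes.
2. **Network construction** — unsigned soft-thresholded adjacency
   `a_ij = |cor(x_i, x_j)|^β`, with β either fixed or chosen as the smallest
   power whose connectivity distribution is approximately scale-free
   (signed fit index R² ≥ 0.90).
3. **Topological overlap** —
   `TOM_ij = (Σ_{k≠i,j} a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
   where `k_i = Σ_{u≠i} a_iu`; genes are clustered by average linkage on
   `1 − TOM` and the tree is cut into modules (minimum size 30, unassigned
   genes labeled *grey*, modules named by the conventional color order).
4. **Module–trait relation** — module eigengenes (ME, the first principal
   component of each module's standardized expression), ME–trait Pearson
   correlations with t-test p-values, gene significance (GS) and module
   significance (MS).
5. **Hub screening** — hub genes are members of the most trait-correlated
   module with |module membership| > 0.8 and |gene–trait correlation| > 0.2.
6. **Validation** — median-split Kaplan–Meier curves with a two-group
   log-rank test, ROC/AUC for tumor vs. normal, Welch t-tests, one-way
   ANOVA, inter-gene correlation, and hypergeometric over-representation
   (ORA) of gene lists in GMT collections with Benjamini–Hochberg control.

A seeded synthetic-data generator plants latent-factor modules, an ordinal
grade trait, expression-driven exponential survival times and tumor/normal
mean shifts, with full ground truth for recovery testing.

## Worked example

```python
from coexnet import SimulationConfig, simulate_expression, WGCNA

cfg = SimulationConfig()                      # 49 samples, modules 100/80/60/40,
expr, traits, truth = simulate_expression(cfg)  # 300 background genes, seed 7
res = WGCNA(expr, traits, power=9, primary_trait="grade").fit()
print(res.summary())
```

prints

```
Weighted co-expression network analysis
========================================
Genes: 580 input, 290 retained by variance filter
Samples: 49
Soft threshold: beta = 9 (fixed)
Modules: 4 (grey/unassigned genes: 14)
  turquoise          98 genes
  blue               79 genes
  brown              60 genes
  yellow             39 genes
Clinically significant module for 'grade': blue (ME-trait r = 0.844, p = 2.8e-14)
Hub genes in blue (|MM| > 0.8, |GS| > 0.2): 46
```

The four planted modules are recovered (adjusted Rand index 0.99 against the
planted labels); the grade-coupled planted module surfaces as **blue** with
ME–grade correlation 0.84, and 46 of its genes pass the hub screen. Hub genes
can then be validated against the simulated survival and tumor/normal tables:

```python
from coexnet import simulate_survival, median_split, logrank_test

surv = simulate_survival(expr, truth, cfg)
groups = median_split(expr.data.loc[truth.survival_gene])
print(logrank_test(surv, groups).p_value)     # 2.5e-05: high expression is adverse
```

The same workflow is scriptable: `coexnet simulate`, `coexnet filter`,
`coexnet network`, `coexnet modules`, `coexnet relate`, `coexnet hubs`,
`coexnet validate`, `coexnet enrich`, or end to end with
`coexnet run-all -o outdir --seed 7` (config via `coexnet init-config`).

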