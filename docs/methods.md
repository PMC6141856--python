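# Methods

## The model

`coexnet` implements unsigned weighted gene co-expression network analysis.
For a genes × samples log-expression matrix X, the co-expression similarity
between genes i and j is `s_ij = |cor(x_i, x_j)|` (Pearson, over samples) and
the network adjacency is the soft-thresholded power

    a_ij = s_ij^β ,  β ≥ 1 integer,  a_ii := 0.

Soft thresholding suppresses weak correlations continuously rather than
cutting at a hard threshold; gene connectivity is `k_i = Σ_{u≠i} a_iu`. The
power can be fixed or selected from a candidate list (default 1..20) as the
smallest power whose connectivity distribution is approximately scale-free.
The scale-free fit index bins k into 10 equal-width bins (k ≤ 0 dropped) and
regresses log10(bin frequency) on log10(bin mean k) over non-empty bins; the
index is the regression R², negated when the slope is positive, so a decaying
power law p(k) ∝ k^(−γ) scores near 1. Selection takes the smallest candidate
with index ≥ 0.90; if none qualifies, the argmax is used and a warning is
emitted.

Shared-neighbor structure is captured by the topological overlap measure

    TOM_ij = ( Σ_{k ∉ {i,j}} a_ik a_kj + a_ij ) / ( min(k_i, k_j) + 1 − a_ij ),
    TOM_ii = 1.

The sum excludes the endpoint genes, which is the standard topological-overlap
convention; with the diagonal of A stored as zero, the matrix-product form
`A·A` yields exactly this sum. TOM lies in [0, 1] and `1 − TOM` is the
clustering dissimilarity.

Genes are clustered by average linkage (UPGMA) on `1 − TOM`. Modules are
obtained by a static branch cut: the tree is cut at a fixed fraction (default
0.99) of its maximum merge height, every branch with at least
`min_module_size` (default 30) leaves becomes a module, and the remaining
genes receive the reserved *grey* label. Modules are named with the
conventional color vocabulary by decreasing size (turquoise, blue, brown, ...),
ties broken by smallest member identifier. This is the "tree" variant of
dynamic tree cut; the hybrid variant (adaptive break-point detection with
PAM-like reassignment by eigengene correlation) is not implemented. That is
the main fidelity gap of the module-detection stage: on real data the hybrid
variant typically yields more, smaller modules, so module counts from this
package are not directly comparable to hybrid-cut counts.

The module eigengene (ME) is the first principal component score of the
module's standardized expression (each gene centered and scaled to unit
variance across samples), unit-normalized and sign-aligned so it correlates
non-negatively with the mean standardized module profile (the sign of a
principal component is otherwise arbitrary, and a fixed convention is needed
for reproducible correlation signs). Module–trait association is the Pearson
correlation of each ME with each numeric trait; all correlation p-values in
the package use the two-sided Student transform `t = r√(n−2)/√(1−r²)` on
n − 2 degrees of freedom, computed by one shared kernel so that every stage
agrees exactly.

Gene significance (GS) is implemented in both of its common forms: the
absolute gene–trait correlation (used for hub screening) and −log10 of the
correlation-test p-value (used for the per-module significance summaries);
module significance (MS) is the mean absolute GS over a module's genes.
Module membership (MM, also kME) is the correlation of a gene with a module
eigengene. A hub gene is a member of the most trait-correlated
("clinically significant") module with |MM| strictly greater than 0.8 and
|gene–trait correlation| strictly greater than 0.2; the inequalities are
strict because boundary genes occur in practice.

## Validation statistics

- **Median split**: samples with expression strictly above the median form
  the "high" group; ties go to "low", so the high group strictly exceeds the
  median.
- **Kaplan–Meier**: product-limit estimation via lifelines; the returned
  curves carry the risk table (at-risk and event counts per time).
- **Log-rank**: computed directly from the pooled risk table — at each
  distinct event time the expected events per group are the hypergeometric
  mean `d·n_g/n` with variance `d(n1/n)(n2/n)(n−d)/(n−1)`; the statistic is
  `(O−E)²/ΣV` on 1 df. This direct form exposes the per-group observed and
  expected counts; agreement with lifelines' test is covered by a unit test.
- **ROC/AUC**: midrank (Mann–Whitney) estimate, equal to the pair-counting
  probability with half-credit for ties.
- **Two-group comparison**: Welch's t-test by default (group variances in
  tumor/normal contrasts are rarely equal); the pooled form is available and
  is the one satisfying the F = t² identity with one-way ANOVA.
- **One-way ANOVA**: fixed-effects between/within decomposition; the fully
  degenerate case (zero between- and within-group variance) is defined to
  return F = 0 with a warning.
- **ORA**: upper-tail hypergeometric p for the overlap of a query list with
  each gene set, sets intersected with the stated universe first,
  Benjamini–Hochberg adjustment across sets, significance at adjusted
  p < 0.001. The universe should be the post-filter gene background.
  This replaces annotation-service lookups with a reproducible, offline
  test over user-supplied GMT collections — a functional, not numerical,
  stand-in for versioned web annotation databases.

## The synthetic-data generator

The generator emulates a microarray-scale tumor cohort with planted
co-expression structure. Defaults (one place, never tuned per test):

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 49 | cohort size of the emulated grade-annotated array study |
| `module_sizes` | (100, 80, 60, 40) | planted module sizes |
| `n_background_genes` | 300 | pure-noise genes |
| `module_loading_range` | (0.6, 0.95) | per-gene loading on the module eigengene |
| `noise_sd` | 0.6 | residual sd around the factor signal |
| `trait_module_index` | 1 | the second-largest module drives grade, so its detected color is *blue* |
| `trait_effect` / `trait_noise_sd` | 2.0 / 1.0 | grade signal-to-noise before discretization |
| `baseline_hazard` | 0.1 | exponential event rate at average expression |
| `survival_log_hazard_coef` | 1.0 | log-hazard per sd of the survival gene |
| `censoring_fraction` | 0.3 | target fraction censored |
| `tumor_fraction` / `tumor_shift` | 0.5 / 2.0 | tumor share and mean shift added to trait-module genes |

Each module m has a latent eigengene e_m (iid normal across samples,
standardized); a planted gene is `loading · e_m + ε`, ε ~ N(0, noise_sd²),
loadings uniform on the loading range. Background genes are N(0, noise_sd²)
noise: their variance sits below every module gene's `loading² + noise_sd²`,
so a top-variance filter preferentially retains planted signal, as it does on
real arrays where informative genes are high-variance. The grade trait is the
tertile discretization (ordinal 1–3, mirroring tumor grading) of
`trait_effect · e_m + noise`. Survival times are exponential with rate
`baseline_hazard · exp(coef · z)`, z the standardized expression of one
designated high-loading gene; censoring is an independent Uniform(0, c)
competitor with c calibrated by root-finding on the drawn event times so the
expected censored fraction hits the target. Tumor labels assign exactly
`round(fraction · n)` samples to the tumor class and add a fixed mean shift
to the trait module's genes. All randomness flows from one seed through named
`numpy.random.Generator` streams (separate streams for expression, survival
and labels), so identical configs give byte-identical tables.

What the generator does **not** emulate: probe-level noise, batch effects,
heavy-tailed and count-based expression distributions, overlapping modules,
hub-dominated ("scale-free") within-module topology, and correlated
background. Passing recovery tests therefore demonstrate correctness of the
pipeline's computations and its behavior under the assumed latent-factor
model, not performance on real cohorts.

One consequence matters for defaults: block-equicorrelated latent-factor data
cannot produce a power-law connectivity distribution at moderate powers, so
the scale-free selection rule on the synthetic cohort keeps raising β until
the network is nearly empty (index first crosses 0.90 around β ≈ 18–20, where
mean connectivity is ~0.1 and no branch survives the size floor). The
end-to-end pipeline therefore defaults to the fixed soft threshold β = 9 —
the value appropriate to the emulated study — while automatic selection
remains available (`power=None` / `--auto-power` style usage) and is the
right choice on real transcriptome-scale data.

## Numerical and design choices

- Variance filtering ranks by per-gene sample variance (denominator n − 1),
  keeps `floor(fraction · n_genes)` genes, and breaks ties lexicographically
  by gene identifier so the cut is deterministic. A 12,413-gene matrix at
  fraction 0.5 retains exactly 6,206 genes.
- Correlations are clipped to [−1, 1] after the vectorized computation to
  guard floating-point overshoot before powering; |r| = 1 maps to p = 0.
- TOM denominators are bounded below by 1 (since min(k_i,k_j) ≥ a_ij), so no
  division guard is needed; results are clipped to [0, 1] against ~1e−16
  overshoot. A `block_size` option computes the shared-neighbor product in
  row blocks with bit-identical results to cap peak memory.
- UPGMA comes from `scipy.cluster.hierarchy.linkage(method="average")`;
  merge heights are checked against a naive O(n³) implementation in the test
  suite. Dendrograms serialize to Newick with branch lengths equal to
  merge-height differences (leaves sit at depth equal to the root height).
- Sample alignment between tables is always by identifier, never by
  position; drops are logged with counts.
- Missing expression values are a hard error by default, with opt-in
  per-gene mean imputation.
- Gene identifiers are opaque (probe IDs or symbols); no annotation mapping
  is attempted.
- The statistics around the network core go through standard libraries
  (scipy, statsmodels, scikit-learn, lifelines); the package's own
  implementations are limited to the network primitives, the tree cut, the
  eigengene machinery and the log-rank risk table, each checked against an
  independent oracle or reference library in the tests.

## Problem sizes used in the checks

The recovery and calibration checks run at the generator defaults
(580 × 49 before filtering, 290 × 49 after) and use 100–200 seeded
replicates of smaller configurations (30–90 genes) for the frequency-based
properties; these sizes make the full suite and the acceptance script run in
seconds while keeping every statistical check comfortably powered.

## Known limitations

- Only the static ("tree") cut variant of dynamic tree cut is implemented;
  module counts on real data will differ from hybrid-variant analyses, and no
  module merging by eigengene similarity is performed.
- Unsigned networks only; signed and signed-hybrid adjacencies are out of
  scope.
- No Cox regression; survival validation is the median-split log-rank
  comparison.
- ORA ignores annotation-graph structure (no GO propagation, no pathway
  topology).
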