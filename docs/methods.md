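# Methods

## Model and procedure

`embedeval` treats a K-dimensional embedding as a multivariate quantitative
trait and scores it on two axes.

**Heritability.** The trait matrix is orthogonalized by PCA on the discovery
cohort (centering, optional unit-variance scaling, eigendecomposition of the
sample covariance via SVD). For each of the first m components a univariate
GWAS is run by OLS of the component on effect-allele dosage plus covariates;
the Wald statistic Z = β̂/SE(β̂) is referred to the standard normal. Because
the components are uncorrelated on the fitting cohort, the per-variant
statistics are asymptotically independent and T = ΣZₖ² is referred to a
central χ² with m degrees of freedom. Variants with p ≤ 5×10⁻⁸ are greedily
LD-clumped (ascending p; each index variant prunes unpruned variants within
the window whose dosage R² exceeds the threshold), and the axis is
summarized by the number of clumped GWS indices and the mean and median T
among them. With no hits, mean/median are reported as null (rendered "–").

**Disease relevance.** For each component separately, the clumped GWS index
variants and their estimated betas form a weights table; a component with no
GWS variant contributes no score, and if no component has one the evaluation
is reported "not evaluable" rather than given a p-value. Scores are raw
weighted allele-count sums computed on the held-out evaluation cohort, which
never enters PCA fitting, GWAS or clumping. A full GLM (all PRS columns +
covariates) and a reduced GLM (covariates only) are fit on the evaluation
cohort; in-sample predictions are summarized by AUROC and average-precision
AUPRC (binary outcome) or squared Pearson correlation and MAE (continuous),
and contrasted as a full/reduced ratio (difference available). The null
distribution of the contrast is obtained by permuting the PRS rows once —
jointly, so inter-PRS correlation survives and only the PRS–outcome link is
destroyed — and refitting both models on B bootstrap resamples of subjects;
p = (1 + #{|Δ_b| ≥ |Δ_obs|})/(1 + B), so the smallest attainable p is
1/(1+B). Ratio contrasts are compared on the log scale so the two-sided
comparison is symmetric; the reported contrast stays a ratio. A variant that
re-permutes inside every resample is available behind
`permute_per_resample=True` for sensitivity analysis; the single up-front
permutation is the default and the documented reading of the procedure.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `m` (components carried to GWAS) | fixed, 5 (or K if smaller) | also available: smallest m reaching a cumulative variance-explained threshold |
| PCA `standardize` | true | embedding dimensions carry arbitrary scales; flag exposed because orthogonalization is valid either way |
| GWS threshold | 5×10⁻⁸ | genome-wide significance, used both for hit counting and PRS inclusion |
| clump `r2_threshold` | 0.1 | LD pruning threshold; 0.5 is the common looser alternative |
| clump `window_kb` | 250 | community default; pairs beyond the window are never pruned |
| relevance `B` | 999 | bootstrap resamples; p-floor 1/(1+B) = 0.001 |
| relevance contrast | ratio | matches the usual reporting convention; difference available |
| PRS standardization | on | PRS columns are z-scored inside the GLM for numerical stability; metrics and p-values are invariant to positive affine rescaling of predictors, so this is presentation-free |

GWAS p-values use the normal reference rather than Student's t (the Wald
statistics are only asymptotically normal anyway); at toy n the normal
reference is slightly anti-conservative — at n = 50 the two-sided p at |z| =
2 differs by about 6% relative. Missing dosages are mean-imputed per variant
before regression and scoring, keeping n constant across variants;
zero-variance (post-imputation) variants are flagged and emitted with β = 0,
p = 1 so downstream stages never divide by zero.

## What the simulator emulates — and what it does not

Genotypes are Binomial(2, MAF) draws, independent across variants (linkage
equilibrium), MAF uniform on [0.05, 0.5], placed 1 Mb apart on one synthetic
chromosome so no pair falls inside a clump window. Each trait component
follows an infinitesimal model on its own disjoint set of n_k causal
variants: β ~ N(0, h²/n_k) on genotypes standardized to mean 0, variance 1,
plus N(0, 1−h²) noise — unit variance and heritability h² in expectation,
uncorrelated across components. The continuous liability adds standardized
components, age (Uniform 40–69) and sex (Bernoulli ½) with coefficients
√(f/f_ε) so each explains exactly its configured variance fraction (10%
each by default). Scenarios: `high_high` (as generated), `high_low`
(liability permuted within each cohort — components stay heritable, outcome
decoupled), `low_low` (trait block and liability permuted independently —
nothing heritable). All randomness flows from one seed through named
substreams; identical configs give bit-identical datasets.

Deliberately absent: LD structure, population stratification, relatedness,
binary disease via liability thresholding, and missingness. Passing the
scenario study therefore shows that the pipeline's statistics behave as
designed under the stated generative model — it does not show robustness to
confounding or LD misspecification, which real cohorts exhibit.

The default study scale is 5,000 discovery + 5,000 evaluation subjects with
2,000 variants, m = 2, n_k = 20 and h² = 0.2, chosen so the per-variant
noncentrality n·h²/n_k = 50 puts causal variants deep in the detectable
regime while the whole study runs in seconds. Two consequences of this
reduced scale are worth noting. First, because infinitesimal-model effect
sizes are themselves random (β² is exponential-like), a sizeable minority of
causal variants draw small effects and stay below genome-wide significance,
so GWS hit counts sit well below the causal count and the captured genetic
variance is below its ceiling. Second, PCA of two standardized,
nearly-uncorrelated components always rotates by ~45°, splitting each causal
variant's signal across both components and trimming per-component PRS
power further (the combined statistic T is rotation-invariant, so the
heritability axis is unaffected). Jointly these push the full/reduced r²
ratio of the high/high scenario slightly below its saturated-power ceiling
of (0.20+0.04)/0.20 = 1.20 — runs land around 1.10–1.17 — and the MAE ratio
slightly above √(0.76/0.80) ≈ 0.97. The scenario *ordering*, which is what
the study is for, is unaffected.

## Numerical choices

* GWAS is vectorized with the Frisch–Waugh–Lovell identity (QR-residualize
  the phenotype and all dosage columns on the covariate design once); this
  is exact OLS and is tested against a per-variant normal-equations loop to
  1e-10.
* Eigenvector signs are fixed so each component's largest-|loading| entry is
  positive; GWAS betas flip with component sign but T and the PRS-based
  relevance test are sign-invariant.
* Clump ties in p are broken by (chrom, pos, id); variant order within
  containers is canonical (chrom lexicographic, then position), subject
  order is sorted id.
* A phenotype numerically fully explained by covariates (e.g. constant)
  yields β = 0, p = 1 for every variant rather than roundoff noise.
* Logistic fits failing on perfect separation fall back to a tiny-L2
  (1e-6) ridge fit, flagged in the log, so the bootstrap loop never aborts.
* A degenerate reduced-model metric of exactly 0 makes the ratio contrast
  undefined; it is reported as inf (or NaN when the full metric is 0 too,
  contributing no evidence). In practice the reduced model always contains
  informative covariates and this path is not exercised.
* Bootstrap resamples under the logistic family are redrawn (up to 100
  times) if a resample loses one outcome class.

## Known limitations

* Wald/normal p-values and the χ²ₘ combination are asymptotic; at very small
  n the per-variant test is mildly anti-conservative.
* Clumping uses the analysis cohort itself as the LD reference; external
  reference panels are not supported.
* The relevance ratio test assumes a non-degenerate baseline model; with an
  empty covariate set and a continuous outcome the reduced r² is 0 by
  convention and the ratio p-value is uninformative (use the difference
  contrast there).
* One evaluation trait per run; survival endpoints and multi-trait
  evaluation are out of scope.
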