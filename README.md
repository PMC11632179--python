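# embedeval

Machine-learning embeddings of rich phenotypes (imaging, omics, wearables)
are increasingly used as quantitative traits in genome-wide association
studies. A trait that yields many genome-wide significant (GWS) hits is not
automatically *useful*: the associated variants may carry no information
about the disease one actually cares about. `embedeval` evaluates a
multivariate trait along two separate axes:

* **Heritability** — how strongly the trait manifests genetic associations:
  the number of independent GWS loci after LD clumping, and the mean/median
  χ² at those loci.
* **Disease relevance** — whether polygenic scores built from the trait's
  associated variants improve prediction of a gold-standard disease label in
  a held-out cohort, over covariates alone.

## Method

Given K trait dimensions Y₁…Y_K, the package orthogonalizes them by PCA and
runs a univariate GWAS for each of the first m ≤ K components,

&nbsp;&nbsp;&nbsp;&nbsp;PCₖ = βₖG + γₖᵀX + ε,

with Wald statistics Zₖ = β̂ₖ/SE(β̂ₖ). Because the components are
orthogonal, the per-variant combined statistic

&nbsp;&nbsp;&nbsp;&nbsp;T = Σₖ Zₖ² ~ χ²ₘ (under H₀)

tests association with *any* component. Significant variants are greedily
LD-clumped (only the lowest-p variant per LD region is retained), giving the
heritability metrics.

For disease relevance, per-component polygenic scores PRSᵢₖ = Σⱼ β̂ⱼGᵢⱼ are
built from each component's clumped GWS variants and carried to a disjoint
evaluation cohort, where a full GLM g{E(D|PRS,X)} = Σₖβₖ·PRSᵢₖ + γᵀXᵢ is
compared with the reduced model g{E(D|X)} = γᵀXᵢ. Prediction quality (AUROC
and AUPRC for binary D; r² and MAE for continuous D) is contrasted as a
full/reduced ratio Δ, and tested against a null built by jointly permuting
the PRS block once and refitting both models on B bootstrap resamples:

&nbsp;&nbsp;&nbsp;&nbsp;p = (1 + Σ_b 1{|Δ_b| ≥ |Δ_obs|}) / (1 + B).

A simulator with a known generative architecture (linkage-equilibrium
genotypes, infinitesimal-model trait components with configurable
heritability, and a linear disease liability) validates that the two axes
are disentangled: permuting the outcome kills relevance but not
heritability; permuting the trait kills both.

## Worked example

Simulate a high-heritability, high-disease-relevance cohort and run the full
evaluation:

```python
from embedeval import run_pipeline

config = {
    "simulation": {
        "n_discovery": 2000, "n_evaluation": 2000, "n_variants": 500,
        "m_pcs": 2, "n_causal": 10, "h2": 0.2, "scenario": "high_high", "seed": 7,
    },
    "pca": {"value": 2},
    "relevance": {"B": 999, "seed": 7},
}
result = run_pipeline(config)
for key, value in result.summary.items():
    print(f"{key}: {value}")
```

prints

```
n_hits: 6
mean_chi2: 54.06461619402696
median_chi2: 57.12416763693645
r2_ratio: 1.097400217331296
r2_p: 0.001
mae_ratio: 0.9860474378739025
mae_p: 0.001
```

Six independent loci reached genome-wide significance (p ≤ 5×10⁻⁸ after
clumping) with a mean combined χ² of 54 — the heritability axis. On the
held-out cohort the per-component polygenic scores raised the squared
correlation of the disease prediction by ~10% (ratio 1.097) and lowered the
MAE (ratio 0.986); both improvements sit at the permutation floor p = 1/(1+B)
= 0.001 — the disease-relevance axis.

The same pipeline is available from the shell, stage by stage or end to end:

```bash
embedeval run-all --config run.yaml --out results/
embedeval simulate|pca|gwas|combine|clump|heritability|prs|relevance|compare --help
```

Every stage reads and writes plain text formats (PLINK 1 bed/bim/fam
genotypes, tab-separated summary statistics with PLINK-style headers,
PLINK-`--score`-compatible weight files, JSON reports), so individual stages
can be swapped for external tools.

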