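"""Synthetic genotypes, embedding PCs and disease liability.

The generator reproduces a known generative architecture so the evaluation
pipeline can be validated against ground truth:

* Variants are drawn in linkage equilibrium — dosages Binomial(2, MAF)
  independently per variant, MAF uniform on a configurable range — and placed
  1 Mb apart on one synthetic chromosome so no pair falls inside any
  realistic clump window.
* Each embedding PC follows an infinitesimal model over its own disjoint set
  of n_k causal variants: effect sizes beta_k ~ N(0, h2/n_k) on genotypes
  standardized to mean 0 / variance 1, plus residual noise N(0, 1 - h2), so
  the PC has unit variance and narrow-sense heritability h2 in expectation.
  Effects are drawn independently across PCs, so the PCs are uncorrelated in
  expectation.
* The continuous disease liability is Y = sum_k gamma_k Z_k + gamma_A Age +
  gamma_S Sex + eps with eps ~ N(0, 1); each component's coefficient is set
  to sqrt(f / f_eps) against its standardized version so that it explains
  exactly its configured fraction f of Var(Y). Age ~ Uniform(40, 69),
  Sex ~ Bernoulli(1/2).

Three validation scenarios:

* ``high_high``   — the dataset as generated (heritable PCs, liability
  depends on them).
* ``high_low``    — Y permuted across subjects (within discovery and
  evaluation separately): PCs stay heritable, outcome no longer depends on
  them.
* ``low_low``     — the Z block and Y both permuted (independent shuffles):
  neither the PCs nor the outcome retain genetic signal.

All randomness flows from the single config seed through named
``SeedSequence`` substreams; an identical config yields a bit-identical
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CohortBundle,
    GenotypeMatrix,
    SubjectTable,
    ValidationError,
    logger,
    make_genotype_matrix,
    write_plink1,
)

SCENARIOS = ("high_high", "high_low", "low_low")

_SUBSTREAMS = ("genotypes", "effects", "noise", "covariates", "liability", "permutation")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the reduced-scale counterpart of the validation study's
    full-scale design: per-variant GWAS noncentrality n*h2/n_k = 5000*0.2/20
    = 50, i.e. the saturated-power regime in which essentially every causal
    variant is genome-wide significant.
    """

    n_discovery: int = 5000
    n_evaluation: int = 5000
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    m_pcs: int = 2
    h2: float = 0.2
    n_causal: int = 20
    pc_fraction: float = 0.1
    age_fraction: float = 0.1
    sex_fraction: float = 0.1
    scenario: str = "high_high"
    seed: int = 0
    variant_spacing_bp: int = 1_000_000

    def validate(self) -> None:
        if not 0 <= self.h2 < 1:
            raise ValidationError(f"h2 must be in [0, 1), got {self.h2}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_causal * self.m_pcs > self.n_variants:
            raise ValidationError(
                f"{self.m_pcs} PCs x {self.n_causal} causal variants exceed "
                f"{self.n_variants} total variants (causal sets are disjoint)"
            )
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"scenario must be one of {SCENARIOS}")
        total = self.m_pcs * self.pc_fraction + self.age_fraction + self.sex_fraction
        if total >= 1:
            raise ValidationError(f"variance fractions sum to {total} >= 1")

    @property
    def n_total(self) -> int:
        return self.n_discovery + self.n_evaluation

    def substreams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


@dataclass
class SimulatedDataset:
    """Discovery and evaluation cohort bundles plus generative ground truth."""

    discovery: CohortBundle
    evaluation: CohortBundle
    truth: dict = field(default_factory=dict)

    def cohort(self, role: str) -> CohortBundle:
        return self.discovery if role == "discovery" else self.evaluation


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Binomial(2, MAF) dosages, independent across variants (linkage equilibrium)."""
    config.validate()
    n, v = config.n_total, config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=v)
    dosages = rng.binomial(2, maf, size=(n, v)).astype(np.float64)
    width = len(str(n - 1))
    subject_ids = np.array([f"S{i:0{width}d}" for i in range(n)], dtype=object)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos_bp": 1 + np.arange(v) * config.variant_spacing_bp,
            "id": [f"var{j:05d}" for j in range(v)],
            "effect_allele": "A",
            "other_allele": "B",
        }
    )
    return make_genotype_matrix(subject_ids, dosages, variants)


def simulate_pcs(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng_effects: np.random.Generator,
    rng_noise: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Infinitesimal-model PCs: Z_k = G_k^std beta_k + eps_k.

    Causal sets are disjoint across PCs and effect vectors independent, so
    cor(Z_j, Z_k) has expectation 0. Candidate causal variants with zero
    dosage variance are excluded up front (cannot carry signal).
    """
    d = genotypes.dosages
    n, v = d.shape
    sd = d.std(axis=0)
    usable = np.nonzero(sd > 0)[0]
    if usable.size < config.n_causal * config.m_pcs:
        raise ValidationError("not enough polymorphic variants for the causal sets")
    if usable.size < v:
        logger.info("simulate_pcs: %d zero-variance variants excluded", v - usable.size)
    chosen = rng_effects.choice(usable, size=config.n_causal * config.m_pcs, replace=False)
    z = np.empty((n, config.m_pcs))
    truth: dict = {"causal_ids": [], "betas": [], "realized_h2": []}
    ids = genotypes.variant_ids
    for k in range(config.m_pcs):
        causal = np.sort(chosen[k * config.n_causal : (k + 1) * config.n_causal])
        g = d[:, causal]
        g_std = (g - g.mean(axis=0)) / g.std(axis=0)
        beta = rng_effects.normal(0.0, np.sqrt(config.h2 / config.n_causal), size=config.n_causal)
        genetic = g_std @ beta
        eps = rng_noise.normal(0.0, np.sqrt(1.0 - config.h2), size=n)
        z[:, k] = genetic + eps
        truth["causal_ids"].append([str(ids[j]) for j in causal])
        truth["betas"].append(beta.tolist())
        truth["realized_h2"].append(float(genetic.var() / z[:, k].var()))
    return z, truth


def simulate_covariates(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Age uniform on [40, 69] and sex Bernoulli(1/2), raw scale."""
    age = rng.uniform(40.0, 69.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    return age, sex


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_liability(
    z: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous liability with each component explaining its configured share."""
    fractions = [config.pc_fraction] * z.shape[1] + [config.age_fraction, config.sex_fraction]
    f_eps = 1.0 - sum(fractions)
    if f_eps <= 0:
        raise ValidationError("variance fractions sum to >= 1")
    components = [z[:, k] for k in range(z.shape[1])] + [age, sex]
    y = rng.normal(0.0, 1.0, size=z.shape[0])
    for f, comp in zip(fractions, components):
        y = y + np.sqrt(f / f_eps) * _standardize(comp)
    return y


def apply_scenario(
    dataset: SimulatedDataset, scenario: str, rng: np.random.Generator
) -> SimulatedDataset:
    """Degrade a ``high_high`` dataset into one of the validation scenarios.

    Permutations are applied within the discovery and evaluation cohorts
    separately so the cohorts stay disjoint and internally consistent.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"scenario must be one of {SCENARIOS}")
    if scenario == "high_high":
        dataset.truth["scenario"] = scenario
        return dataset
    z_cols = [c for c in dataset.discovery.tables[0].columns if c.startswith("Z")]
    for bundle in (dataset.discovery, dataset.evaluation):
        df = bundle.tables[0].data
        n = len(df)
        if scenario in ("high_low", "low_low"):
            df["Y"] = df["Y"].to_numpy()[rng.permutation(n)]
        if scenario == "low_low":
            perm = rng.permutation(n)  # one joint shuffle of the Z block
            df[z_cols] = df[z_cols].to_numpy()[perm]
    dataset.truth["scenario"] = scenario
    return dataset


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end generation of a scenario dataset from a single seed."""
    config.validate()
    rngs = config.substreams()
    genotypes = simulate_genotypes(config, rngs["genotypes"])
    z, truth = simulate_pcs(genotypes, config, rngs["effects"], rngs["noise"])
    age, sex = simulate_covariates(config.n_total, rngs["covariates"])
    y = simulate_liability(z, age, sex, config, rngs["liability"])

    table = pd.DataFrame(
        {f"Z{k + 1}": z[:, k] for k in range(config.m_pcs)},
        index=genotypes.subject_ids,
    )
    table["age"] = age
    table["sex"] = sex
    table["Y"] = y

    ids = list(genotypes.subject_ids)
    disc_ids, eval_ids = ids[: config.n_discovery], ids[config.n_discovery :]
    bundles = {}
    for role, cohort_ids in (("discovery", disc_ids), ("evaluation", eval_ids)):
        bundles[role] = CohortBundle(
            genotypes=genotypes.subset_subjects(cohort_ids),
            tables=[SubjectTable(table.loc[cohort_ids])],
            role=role,
        )
    truth["config"] = asdict(config)
    dataset = SimulatedDataset(discovery=bundles["discovery"], evaluation=bundles["evaluation"], truth=truth)
    return apply_scenario(dataset, config.scenario, rngs["permutation"])


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write each cohort as a PLINK 1 triple plus a subject TSV, and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for role in ("discovery", "evaluation"):
        bundle = dataset.cohort(role)
        write_plink1(bundle.genotypes, outdir / role)
        bundle.tables[0].to_tsv(outdir / f"{role}.subjects.tsv")
    (outdir / "truth.json").write_text(json.dumps(dataset.truth, indent=1))
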