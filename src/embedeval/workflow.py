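"""End-to-end orchestration of the two-axis evaluation.

A single run takes a multivariate trait (simulated or from files), scores its
heritability on the discovery cohort (PCA -> per-PC GWAS -> chi-square
combination -> LD clumping -> hit counting) and its disease relevance on the
held-out evaluation cohort (per-PC clump -> PRS weights -> scoring ->
permutation-bootstrap nested-GLM test), writing every intermediate in a
documented text format so external tools can be swapped in per stage.

Runs are deterministic given the config seed; a manifest records input
config hash, per-stage wall time and a checksum for every written file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    CohortBundle,
    SubjectTable,
    ValidationError,
    align_cohort,
    impute_missing_dosages,
    logger,
    read_genotypes,
)
from .gwas import UnivariateSummaryStats, batch_gwas
from .multivariate import (
    GWS_P,
    HeritabilityReport,
    MultivariateSummaryStats,
    clump,
    combine_stats,
    heritability_metrics,
    pairwise_r2,
)
from .orthogonalize import fit_pca, select_m, transform
from .prs import PRSTable, build_weights, score_all
from .relevance import RelevanceReport, relevance_test
from .simulator import SimulationConfig, simulate_dataset

DEFAULTS = {
    "pca": {"standardize": True, "policy": "fixed", "value": None},
    "gwas": {"covariates": []},
    "clump": {"p1": GWS_P, "r2_threshold": 0.1, "window_kb": 250.0, "gws_p": GWS_P},
    "relevance": {
        "covariates": ["age", "sex"],
        "outcome": "Y",
        "family": "linear",
        "B": 999,
        "contrast": "ratio",
        "seed": 0,
    },
}


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int | None
    version: str
    stages: list = field(default_factory=list)  # {name, wall_time_s, outputs: {path: sha256}}

    def add_stage(self, name: str, wall_time_s: float, outputs: dict | None = None) -> None:
        self.stages.append(
            {"name": name, "wall_time_s": round(wall_time_s, 4), "outputs": outputs or {}}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    def verify(self) -> bool:
        """True when every recorded output still exists with its checksum."""
        for stage in self.stages:
            for p, digest in stage["outputs"].items():
                if not Path(p).exists() or _sha256(p) != digest:
                    return False
        return True


@dataclass
class PipelineResult:
    """Reports plus enough context to compare runs."""

    heritability: HeritabilityReport
    relevance: RelevanceReport
    manifest: RunManifest
    summary: dict
    multivariate_stats: MultivariateSummaryStats
    per_pc_stats: list[UnivariateSummaryStats]
    prs: PRSTable
    evaluation_subject_ids: list


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _merged(section: str, config: dict) -> dict:
    out = dict(DEFAULTS[section])
    out.update(config.get(section, {}))
    return out


def _load_cohorts(config: dict) -> tuple[CohortBundle, CohortBundle, list[str]]:
    """Materialize discovery/evaluation bundles from a simulation block or files."""
    if "simulation" in config:
        sim = SimulationConfig(**config["simulation"])
        dataset = simulate_dataset(sim)
        trait_cols = [f"Z{k + 1}" for k in range(sim.m_pcs)]
        return dataset.discovery, dataset.evaluation, trait_cols
    data = config["data"]
    genotypes = read_genotypes(data["genotypes"], data.get("format", "plink1"))
    embeddings = SubjectTable.from_tsv(data["embeddings"])
    tables = [embeddings]
    for key in ("covariates", "labels"):
        if data.get(key):
            tables.append(SubjectTable.from_tsv(data[key]))
    disc_ids = set(Path(data["discovery_ids"]).read_text().split())
    eval_ids = set(Path(data["evaluation_ids"]).read_text().split())
    if disc_ids & eval_ids:
        raise ValidationError("discovery and evaluation subject sets overlap")
    trait_cols = data.get("embedding_columns") or embeddings.columns
    bundles = []
    for role, keep in (("discovery", disc_ids), ("evaluation", eval_ids)):
        g = genotypes.subset_subjects(sorted(set(genotypes.subject_ids) & keep))
        bundles.append(align_cohort(g, *tables, role=role))
    return bundles[0], bundles[1], trait_cols


def run_pipeline(config: dict, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full two-axis evaluation described by ``config``."""
    t0 = time.perf_counter()
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    rel_cfg = _merged("relevance", config)
    manifest = RunManifest(config_hash=config_hash, seed=rel_cfg.get("seed"), version=__version__)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def record(name: str, started: float, files: list[Path] | None = None) -> None:
        outputs = {str(f): _sha256(f) for f in (files or [])}
        manifest.add_stage(name, time.perf_counter() - started, outputs)

    # ---- inputs -----------------------------------------------------------
    t = time.perf_counter()
    discovery, evaluation, trait_cols = _load_cohorts(config)
    discovery.genotypes = impute_missing_dosages(discovery.genotypes)
    evaluation.genotypes = impute_missing_dosages(evaluation.genotypes)
    record("load", t)

    # ---- orthogonalize ----------------------------------------------------
    t = time.perf_counter()
    pca_cfg = _merged("pca", config)
    traits_disc = discovery.table(*trait_cols)
    model = fit_pca(traits_disc, standardize=pca_cfg["standardize"])
    m_value = pca_cfg["value"] if pca_cfg["value"] is not None else min(model.k, 5)
    m = select_m(model, pca_cfg["policy"], m_value)
    pcs_disc = transform(traits_disc, model, m)
    files = []
    if out is not None:
        model.to_json(out / "pc_model.json")
        pcs_disc.to_tsv(out / "pc_scores.discovery.tsv")
        files = [out / "pc_model.json", out / "pc_scores.discovery.tsv"]
    record("orthogonalize", t, files)

    # ---- per-PC GWAS ------------------------------------------------------
    t = time.perf_counter()
    gwas_cfg = _merged("gwas", config)
    covariates = (
        discovery.table(*gwas_cfg["covariates"]) if gwas_cfg["covariates"] else None
    )
    per_pc = batch_gwas(pcs_disc, discovery.genotypes, covariates)
    files = []
    if out is not None:
        for s in per_pc:
            f = out / f"gwas.pc{s.pc_index}.tsv"
            s.to_tsv(f)
            files.append(f)
    record("gwas", t, files)

    # ---- combine / clump / heritability ----------------------------------
    t = time.perf_counter()
    clump_cfg = _merged("clump", config)
    mv = combine_stats(per_pc)
    ld = pairwise_r2(discovery.genotypes, clump_cfg["window_kb"])
    mv_clumps = clump(
        mv, ld, clump_cfg["p1"], clump_cfg["r2_threshold"], clump_cfg["window_kb"]
    )
    herit = heritability_metrics(mv, mv_clumps, clump_cfg["gws_p"])
    files = []
    if out is not None:
        mv.to_tsv(out / "multivariate.tsv")
        mv_clumps.to_tsv(mv, out / "clumped.multivariate.tsv")
        herit.to_json(out / "heritability.json")
        files = [out / "multivariate.tsv", out / "clumped.multivariate.tsv", out / "heritability.json"]
    record("heritability", t, files)

    # ---- per-PC PRS -------------------------------------------------------
    t = time.perf_counter()
    weights = []
    for s in per_pc:
        pc_clumps = clump(s, ld, clump_cfg["p1"], clump_cfg["r2_threshold"], clump_cfg["window_kb"])
        weights.append(build_weights(s, pc_clumps, clump_cfg["gws_p"]))
    prs = score_all(evaluation.genotypes, weights)
    files = []
    if out is not None:
        for w in weights:
            f = out / f"weights.pc{w.pc_index}.tsv"
            w.to_tsv(f)
            files.append(f)
        prs.to_tsv(out / "prs.evaluation.tsv")
        files.append(out / "prs.evaluation.tsv")
    record("prs", t, files)

    # ---- relevance --------------------------------------------------------
    t = time.perf_counter()
    d_eval = evaluation.table(rel_cfg["outcome"])[rel_cfg["outcome"]].to_numpy(dtype=float)
    rel_cov = evaluation.table(*rel_cfg["covariates"]) if rel_cfg["covariates"] else None
    relevance = relevance_test(
        d_eval,
        prs,
        rel_cov,
        family=rel_cfg["family"],
        B=rel_cfg["B"],
        contrast=rel_cfg["contrast"],
        seed=rel_cfg["seed"],
    )
    files = []
    if out is not None:
        relevance.to_json(out / "relevance.json")
        files = [out / "relevance.json"]
    record("relevance", t, files)

    summary = summarize(herit, relevance)
    if out is not None:
        pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest.add_stage("summary", 0.0, {str(out / "summary.tsv"): _sha256(out / "summary.tsv")})
        manifest.to_json(out / "manifest.json")
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return PipelineResult(
        heritability=herit,
        relevance=relevance,
        manifest=manifest,
        summary=summary,
        multivariate_stats=mv,
        per_pc_stats=per_pc,
        prs=prs,
        evaluation_subject_ids=list(evaluation.subject_ids),
    )


def summarize(herit: HeritabilityReport, relevance: RelevanceReport) -> dict:
    """One flat row with the standard two-axis column layout."""
    row = {
        "n_hits": herit.n_gws_hits,
        "mean_chi2": herit.mean_chi2 if herit.mean_chi2 is not None else "-",
        "median_chi2": herit.median_chi2 if herit.median_chi2 is not None else "-",
    }
    metric_names = (
        ("auroc", "auprc") if relevance.family == "logistic" else ("r2", "mae")
    )
    for name in metric_names:
        if relevance.evaluable and name in relevance.metrics:
            mc = relevance.metrics[name]
            row[f"{name}_{mc.contrast_type}"] = mc.delta_obs
            row[f"{name}_p"] = mc.p_value
        else:
            row[f"{name}_ratio"] = "-"
            row[f"{name}_p"] = "-"
    return row


def compare_embeddings(results: list[PipelineResult], names: list[str] | None = None) -> pd.DataFrame:
    """Side-by-side comparison of completed runs on the same evaluation cohort.

    Rows are reported on both axes; no composite ranking score is computed.
    """
    if len(results) < 2:
        raise ValidationError("need at least two completed runs to compare")
    ref = results[0].evaluation_subject_ids
    for r in results[1:]:
        if r.evaluation_subject_ids != ref:
            raise ValidationError("runs evaluate different cohorts; comparison is invalid")
    names = names or [f"run{i + 1}" for i in range(len(results))]
    rows = []
    for name, r in zip(names, results):
        rows.append({"embedding": name, **r.summary})
    return pd.DataFrame(rows)
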