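"""Per-PC polygenic risk scores from clumped genome-wide significant variants.

A PC's score for subject i is the plain weighted allele-count sum

    PRS_i = sum_j beta_j * G_ij,

where the weights are the discovery-cohort GWAS betas at that PC's clumped
GWS index variants. A PC with no GWS variant yields an empty weights table;
its PRS column is absent and the disease-relevance evaluation skips it.
Scores are raw sums (not averaged per allele) and a single p-value threshold
(genome-wide significance) is used — no threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, ValidationError, logger
from .gwas import UnivariateSummaryStats
from .multivariate import GWS_P, ClumpedSet


@dataclass
class WeightsTable:
    """Effect-allele weights (discovery betas) at one PC's GWS clump indices."""

    pc_index: int
    table: pd.DataFrame  # id, chrom, pos_bp, effect_allele, weight

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def empty(self) -> bool:
        return len(self.table) == 0

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "ID": self.table["id"],
                "A1": self.table["effect_allele"],
                "BETA": self.table["weight"],
            }
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class PRSTable:
    """Subjects x PCs score matrix with per-column variant counts."""

    subject_ids: np.ndarray
    scores: pd.DataFrame  # columns PRS_PC<k>
    provenance: dict  # column -> number of contributing variants

    @property
    def columns(self) -> list[str]:
        return list(self.scores.columns)

    def informative_columns(self) -> list[str]:
        return [c for c in self.scores.columns if self.provenance.get(c, 0) > 0]

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="subject_id")


def build_weights(
    per_pc_stats: UnivariateSummaryStats,
    per_pc_clumps: ClumpedSet,
    gws_p: float = GWS_P,
) -> WeightsTable:
    """Weights = estimated beta at each GWS clump index variant for this PC."""
    t = per_pc_stats.table.set_index("id")
    rows = []
    for vid in per_pc_clumps.index_variants:
        rec = t.loc[vid]
        if rec["p"] <= gws_p:
            rows.append(
                {
                    "id": vid,
                    "chrom": rec["chrom"],
                    "pos_bp": int(rec["pos_bp"]),
                    "effect_allele": rec["effect_allele"],
                    "weight": float(rec["beta"]),
                }
            )
    table = pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "effect_allele", "weight"])
    if len(table):
        table = table.sort_values(["chrom", "pos_bp", "id"], kind="mergesort").reset_index(drop=True)
    else:
        logger.info("PC%d: no GWS variant; empty weights table", per_pc_stats.pc_index)
    return WeightsTable(pc_index=per_pc_stats.pc_index, table=table)


def score(
    genotypes_eval: GenotypeMatrix,
    weights: WeightsTable,
    allele_policy: str = "strict",
) -> np.ndarray:
    """Score evaluation-cohort subjects: PRS_i = sum_j beta_j * dosage_ij.

    Under ``flip``, a variant whose effect/other alleles are swapped relative
    to the evaluation panel contributes ``beta * (2 - g)``.
    """
    if allele_policy not in ("strict", "flip"):
        raise ValueError(f"unknown allele policy {allele_policy!r}")
    if weights.empty:
        return np.zeros(genotypes_eval.n_subjects)
    v = genotypes_eval.variants.set_index("id")
    missing = [vid for vid in weights.table["id"] if vid not in v.index]
    if missing:
        raise ValidationError(f"weight variants absent from evaluation genotypes: {missing}")
    col_of = {vid: j for j, vid in enumerate(genotypes_eval.variant_ids)}
    total = np.zeros(genotypes_eval.n_subjects)
    for rec in weights.table.itertuples():
        panel = v.loc[rec.id]
        g = genotypes_eval.dosages[:, col_of[rec.id]]
        if panel["effect_allele"] == rec.effect_allele:
            total += rec.weight * g
        elif allele_policy == "flip" and panel["other_allele"] == rec.effect_allele:
            total += rec.weight * (2.0 - g)
        else:
            raise ValidationError(
                f"allele mismatch at {rec.id}: weights use {rec.effect_allele}, "
                f"panel has {panel['effect_allele']}/{panel['other_allele']}"
            )
    return total


def score_all(
    genotypes_eval: GenotypeMatrix,
    weights_list: list[WeightsTable],
    allele_policy: str = "strict",
) -> PRSTable:
    """Build the full subjects x PCs PRS table (one column per weights table)."""
    cols, prov = {}, {}
    for w in weights_list:
        name = f"PRS_PC{w.pc_index}"
        cols[name] = score(genotypes_eval, w, allele_policy)
        prov[name] = w.n_variants
    scores = pd.DataFrame(cols, index=genotypes_eval.subject_ids)
    return PRSTable(subject_ids=genotypes_eval.subject_ids, scores=scores, provenance=prov)
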