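"""Per-PC univariate GWAS by ordinary least squares.

Each variant is tested one at a time with the linear model

    PC_k = b0 + beta * G + gamma' X + e,

where G is the effect-allele dosage and X an optional covariate matrix. The
Wald statistic z = beta_hat / SE(beta_hat) is referred to the standard normal
(the large-sample reference; per-component statistics are asymptotically
normal and, because the PCs are orthogonal, independent across components).
With toy-sized n the normal reference is mildly anti-conservative relative to
the t distribution — deliberate, and documented in the methods note.

The per-variant fits are vectorized with the Frisch–Waugh–Lovell identity:
residualize the phenotype and every dosage column on the covariate design
once, then each variant's slope is a one-dimensional regression of residuals.
This is algebraically exact OLS, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeMatrix, ValidationError
from .orthogonalize import PCMatrix

SUMSTAT_HEADER = ["#CHROM", "POS", "ID", "A1", "OBS_CT", "BETA", "SE", "T_STAT", "P"]


@dataclass
class UnivariateSummaryStats:
    """Per-variant OLS association records for one PC."""

    pc_index: int  # 1-based
    table: pd.DataFrame  # id, chrom, pos_bp, effect_allele, n, beta, se, z, p, zero_var

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "#CHROM": self.table["chrom"],
                "POS": self.table["pos_bp"],
                "ID": self.table["id"],
                "A1": self.table["effect_allele"],
                "OBS_CT": self.table["n"],
                "BETA": self.table["beta"],
                "SE": self.table["se"],
                "T_STAT": self.table["z"],
                "P": self.table["p"],
            }
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, pc_index: int) -> "UnivariateSummaryStats":
        df = pd.read_csv(path, sep="\t", dtype={"#CHROM": str, "ID": str, "A1": str})
        table = pd.DataFrame(
            {
                "id": df["ID"],
                "chrom": df["#CHROM"],
                "pos_bp": df["POS"].astype(int),
                "effect_allele": df["A1"],
                "n": df["OBS_CT"].astype(int),
                "beta": df["BETA"].astype(float),
                "se": df["SE"].astype(float),
                "z": df["T_STAT"].astype(float),
                "p": df["P"].astype(float),
            }
        )
        table["zero_var"] = ~np.isfinite(table["se"].to_numpy())
        return cls(pc_index=pc_index, table=table)


def _covariate_design(n: int, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """Intercept-prepended covariate design with a full-rank check."""
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return np.ones((n, 1)), ["intercept"]
    c = np.asarray(covariates, dtype=float)
    if c.shape[0] != n:
        raise ValidationError(f"covariates have {c.shape[0]} rows, expected {n}")
    names = ["intercept"] + [str(col) for col in covariates.columns]
    design = np.column_stack([np.ones(n), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = cand
        raise ValidationError(f"collinear covariate columns: {bad}")
    return design, names


def run_gwas(
    pc_scores: np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    pc_index: int = 1,
) -> UnivariateSummaryStats:
    """OLS association of one PC against every variant.

    Requires an aligned, imputed cohort (no missing dosages), so the sample
    size n is identical across variants. Variants with zero post-imputation
    dosage variance are emitted with beta 0, p 1 and flagged.
    """
    y = np.asarray(pc_scores, dtype=float)
    g = genotypes.dosages
    n = y.shape[0]
    if g.shape[0] != n:
        raise ValidationError("pc_scores length does not match genotype subjects")
    if np.isnan(g).any():
        raise ValidationError("genotypes contain missing dosages; impute first")
    design, _ = _covariate_design(n, covariates)
    q = design.shape[1]
    if n < q + 2:
        raise ValidationError(f"need at least {q + 2} subjects, have {n}")

    # orthonormal basis of the covariate space; residualize y and G against it
    qmat, _ = np.linalg.qr(design)
    y_res = y - qmat @ (qmat.T @ y)
    g_res = g - qmat @ (qmat.T @ g)

    sxx = np.einsum("ij,ij->j", g_res, g_res)
    sxy = g_res.T @ y_res
    syy = float(y_res @ y_res)
    df = n - q - 1

    if syy <= (float(y @ y) + 1.0) * 1e-24:
        # phenotype fully explained by covariates (e.g. constant): nothing to test
        y_res = np.zeros_like(y_res)
        sxy = np.zeros_like(sxy)
        syy = 0.0

    zero_var = sxx <= n * 1e-24
    safe_sxx = np.where(zero_var, 1.0, sxx)
    beta = np.where(zero_var, 0.0, sxy / safe_sxx)
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / safe_sxx)
    se = np.where(zero_var, np.inf, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se == 0, 1.0, se), 0.0)
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(zero_var | (se == 0), 1.0, np.clip(p, np.nextafter(0, 1), 1.0))

    table = pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "chrom": genotypes.variants["chrom"],
            "pos_bp": genotypes.variants["pos_bp"],
            "effect_allele": genotypes.variants["effect_allele"],
            "n": n,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "zero_var": zero_var,
        }
    )
    return UnivariateSummaryStats(pc_index=pc_index, table=table)


def batch_gwas(
    pcs: PCMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
) -> list[UnivariateSummaryStats]:
    """Run :func:`run_gwas` for every PC column; results match the one-at-a-time loop."""
    return [
        run_gwas(pcs.column(k), genotypes, covariates, pc_index=k + 1)
        for k in range(pcs.m)
    ]
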