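"""Disease-relevance evaluation: do the per-PC polygenic scores improve
prediction of a gold-standard disease label over covariates alone?

Two nested generalized linear models are fit on the held-out evaluation
cohort:

    full:    g(E[D | PRS, X]) = sum_k beta_k PRS_k + gamma' X
    reduced: g(E[D | X])      = gamma' X

(identity link / OLS for a continuous label, logit link / maximum likelihood
for a binary one). In-sample predictions from each model are summarized by
AUROC and AUPRC (binary) or squared Pearson correlation and mean absolute
error (continuous), and the full/reduced contrast Delta (ratio by default) is
tested against a permutation null: the PRS block is row-permuted once,
rendering it non-informative while preserving inter-PRS correlation, and B
bootstrap resamples of subjects are drawn; both models are refit on each
resample and the null contrast recorded. The p-value is

    p = (1 + #{|Delta_b| >= |Delta_obs|}) / (1 + B),

with ratio contrasts compared on the log scale so the two-sided comparison is
symmetric. The smallest attainable p is therefore 1/(1+B).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, roc_auc_score

from .datamodel import ValidationError, logger
from .prs import PRSTable

_RIDGE_ALPHA = 1e-6  # tiny L2 fallback so resampling never aborts on separation


@dataclass
class GLMSpec:
    """Which model to fit: family, outcome column, covariates, PRS columns."""

    family: str  # linear | logistic
    outcome: str
    covariates: list[str] = field(default_factory=list)
    prs_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValidationError(f"unknown GLM family {self.family!r}")


@dataclass
class MetricContrast:
    """Full/reduced values of one metric with its permutation-bootstrap p."""

    metric: str
    value_full: float
    value_reduced: float
    delta_obs: float
    contrast_type: str
    p_value: float
    B: int
    null_deltas: np.ndarray


@dataclass
class RelevanceReport:
    """Outcome of the disease-relevance test for one embedding."""

    evaluable: bool
    family: str
    contrast_type: str
    B: int
    seed: int | None
    n_prs_columns: int
    metrics: dict = field(default_factory=dict)  # name -> MetricContrast

    def to_json(self, path: str | Path) -> None:
        obj = {
            "evaluable": self.evaluable,
            "family": self.family,
            "contrast": self.contrast_type,
            "B": self.B,
            "seed": self.seed,
            "n_prs_columns": self.n_prs_columns,
            "metrics": {
                name: {
                    "full": mc.value_full,
                    "reduced": mc.value_reduced,
                    "delta": mc.delta_obs,
                    "p": mc.p_value,
                }
                for name, mc in self.metrics.items()
            },
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _design(data: pd.DataFrame, columns: list[str]) -> np.ndarray:
    return np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in columns])


def _predict_linear(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return x @ coef


def _predict_logistic(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """ML logistic fit; tiny-ridge fallback on separation / non-convergence."""
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("logistic family requires a {0,1}-coded outcome")
    if len(np.unique(y)) < 2:
        raise ValidationError("logistic family requires both classes present")
    model = sm.GLM(y, x, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = model.fit(maxiter=100)
        mu = np.asarray(res.mu)
        if not np.all(np.isfinite(res.params)) or np.any(mu <= 0) or np.any(mu >= 1):
            raise RuntimeError("degenerate fitted probabilities")
        return mu
    except Exception:  # separation / non-convergence
        logger.info("logistic fit failed (likely separation); ridge fallback")
        res = model.fit_regularized(alpha=_RIDGE_ALPHA, L1_wt=0.0)
        eta = x @ np.asarray(res.params)
        return 1.0 / (1.0 + np.exp(-eta))


def _predict(y: np.ndarray, x: np.ndarray, family: str) -> np.ndarray:
    return _predict_linear(y, x) if family == "linear" else _predict_logistic(y, x)


def fit_and_predict(spec: GLMSpec, data: pd.DataFrame) -> np.ndarray:
    """Fit the GLM and return in-sample predictions.

    Linear: OLS fitted values. Logistic: maximum-likelihood fitted
    probabilities; if the fit fails (e.g. perfect separation) a ridge fit with
    a tiny L2 penalty is used instead, and the event logged.
    """
    y = data[spec.outcome].to_numpy(dtype=float)
    x = _design(data, spec.covariates + spec.prs_columns)
    return _predict(y, x, spec.family)


def evaluate_metrics(d: np.ndarray, d_hat: np.ndarray, family: str) -> dict:
    """Binary: AUROC and AUPRC (average precision). Continuous: r^2 and MAE."""
    d = np.asarray(d, dtype=float)
    d_hat = np.asarray(d_hat, dtype=float)
    if d.shape != d_hat.shape:
        raise ValidationError("label and prediction lengths differ")
    if family == "logistic":
        if len(np.unique(d)) < 2:
            raise ValidationError("binary metrics require both classes")
        return {
            "auroc": float(roc_auc_score(d, d_hat)),
            "auprc": float(average_precision_score(d, d_hat)),
        }
    if np.std(d_hat) == 0 or np.std(d) == 0:
        logger.info("zero-variance predictions or labels; r2 set to 0")
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(d, d_hat)[0, 1] ** 2)
    return {"r2": r2, "mae": float(np.mean(np.abs(d - d_hat)))}


def _contrast(full: float, reduced: float, contrast: str) -> tuple[float, float]:
    """Return (reported delta, symmetric-scale delta used for the test)."""
    if contrast == "difference":
        delta = full - reduced
        return delta, delta
    if reduced == 0:
        # degenerate baseline: no evidence if full is 0 too, else maximal
        return (float("nan"), 0.0) if full == 0 else (float("inf"), float("inf"))
    ratio = full / reduced
    starred = float(np.log(ratio)) if ratio > 0 else float("inf")
    return float(ratio), starred


def _metric_contrasts(
    d: np.ndarray, x_full: np.ndarray, x_red: np.ndarray, family: str, contrast: str
) -> dict:
    """Fit both nested models on (d, designs) and contrast their metrics."""
    m_full = evaluate_metrics(d, _predict(d, x_full, family), family)
    m_red = evaluate_metrics(d, _predict(d, x_red, family), family)
    out = {}
    for name in m_full:
        delta, starred = _contrast(m_full[name], m_red[name], contrast)
        out[name] = (m_full[name], m_red[name], delta, starred)
    return out


def relevance_test(
    d: np.ndarray | pd.Series,
    prs: PRSTable,
    covariates: pd.DataFrame | None,
    family: str = "linear",
    B: int = 999,
    contrast: str = "ratio",
    seed: int | None = None,
    permute_per_resample: bool = False,
    standardize_prs: bool = True,
) -> RelevanceReport:
    """Permutation-plus-bootstrap test of the PRS block's incremental value.

    The PRS columns are permuted jointly (one row shuffle) so their mutual
    correlation survives under the null; only the PRS-outcome link is
    destroyed. ``permute_per_resample`` redraws the permutation inside every
    bootstrap iteration instead (sensitivity variant; the default permutes
    once up front).
    """
    if contrast not in ("ratio", "difference"):
        raise ValueError(f"unknown contrast {contrast!r}")
    informative = prs.informative_columns()
    if not informative:
        logger.info("no informative PRS column; relevance not evaluable")
        return RelevanceReport(
            evaluable=False, family=family, contrast_type=contrast, B=B, seed=seed,
            n_prs_columns=0,
        )
    y = np.asarray(d, dtype=float)
    n = len(y)
    p_mat = prs.scores[informative].to_numpy(dtype=float)
    if standardize_prs:
        sd = p_mat.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        p_mat = (p_mat - p_mat.mean(axis=0)) / sd
    if covariates is not None and len(covariates) != n:
        raise ValidationError("covariate rows do not match outcome length")
    x_cov = (
        np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        if covariates is not None and covariates.shape[1] > 0
        else np.ones((n, 1))
    )
    x_full = np.column_stack([x_cov, p_mat])

    observed = _metric_contrasts(y, x_full, x_cov, family, contrast)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    p_perm = p_mat[perm]
    null_starred: dict[str, list[float]] = {k: [] for k in observed}
    null_deltas: dict[str, list[float]] = {k: [] for k in observed}
    for _ in range(B):
        if permute_per_resample:
            p_perm = p_mat[rng.permutation(n)]
        idx = rng.integers(0, n, n)
        if family == "logistic":
            # resample until both classes present (degenerate metric otherwise)
            tries = 0
            while len(np.unique(y[idx])) < 2 and tries < 100:
                idx = rng.integers(0, n, n)
                tries += 1
        xb_cov = x_cov[idx]
        xb_full = np.column_stack([xb_cov, p_perm[idx]])
        boot = _metric_contrasts(y[idx], xb_full, xb_cov, family, contrast)
        for name, (_, _, delta, starred) in boot.items():
            null_deltas[name].append(delta)
            null_starred[name].append(starred)

    report = RelevanceReport(
        evaluable=True, family=family, contrast_type=contrast, B=B, seed=seed,
        n_prs_columns=len(informative),
    )
    for name, (v_full, v_red, delta_obs, starred_obs) in observed.items():
        nulls = np.asarray(null_starred[name], dtype=float)
        exceed = np.abs(nulls) >= abs(starred_obs)
        exceed = np.where(np.isnan(nulls), True, exceed)  # undefined nulls count against
        p_val = (1 + int(exceed.sum())) / (1 + B)
        report.metrics[name] = MetricContrast(
            metric=name,
            value_full=v_full,
            value_reduced=v_red,
            delta_obs=delta_obs,
            contrast_type=contrast,
            p_value=p_val,
            B=B,
            null_deltas=np.asarray(null_deltas[name], dtype=float),
        )
    return report
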