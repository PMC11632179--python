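"""Orthogonalize a K-dimensional trait/embedding matrix via PCA.

Embedding dimensions are typically correlated; per-dimension association
statistics would not be independent and could not be combined into a simple
chi-square. Principal components are uncorrelated on the fitting cohort by
construction, which is what licenses summing squared Wald statistics
downstream.

The model is always fit on the discovery cohort and the stored
center/scale/loadings are reused to project evaluation-cohort subjects, so no
evaluation information leaks into discovery-side statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ValidationError


@dataclass
class PCModel:
    """Fitted PCA: column center/scale plus an orthonormal loading matrix.

    ``variance_explained`` is the normalized eigenvalue spectrum
    (non-increasing, sums to 1).
    """

    center: np.ndarray
    scale: np.ndarray | None
    loadings: np.ndarray  # K x K, columns are components
    variance_explained: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        k = self.loadings.shape[0]
        if self.loadings.shape != (k, k):
            raise ValidationError("loadings must be square (K x K)")
        if not np.allclose(self.loadings.T @ self.loadings, np.eye(k), atol=1e-8):
            raise ValidationError("loadings are not orthonormal")
        ve = self.variance_explained
        if np.any(ve < -1e-12) or np.any(np.diff(ve) > 1e-12):
            raise ValidationError("variance_explained must be non-negative, non-increasing")

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "center": self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "column_names": self.column_names,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            center=np.array(obj["center"], dtype=float),
            scale=None if obj["scale"] is None else np.array(obj["scale"], dtype=float),
            loadings=np.array(obj["loadings"], dtype=float),
            variance_explained=np.array(obj["variance_explained"], dtype=float),
            column_names=list(obj["column_names"]),
        )


@dataclass
class PCMatrix:
    """Subjects x m matrix of PC scores (mean-centered on the fitting cohort)."""

    subject_ids: np.ndarray
    components: np.ndarray  # n x m
    m: int

    def __post_init__(self) -> None:
        if self.components.shape != (len(self.subject_ids), self.m):
            raise ValidationError("components shape does not match (n_subjects, m)")

    def column(self, k: int) -> np.ndarray:
        return self.components[:, k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.components,
            index=self.subject_ids,
            columns=[f"PC{i + 1}" for i in range(self.m)],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="subject_id")


def _as_matrix(traits: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str], np.ndarray]:
    if isinstance(traits, pd.DataFrame):
        return (
            traits.to_numpy(dtype=float),
            [str(c) for c in traits.columns],
            traits.index.to_numpy(dtype=object),
        )
    arr = np.asarray(traits, dtype=float)
    names = [f"Y{i + 1}" for i in range(arr.shape[1])]
    return arr, names, np.arange(arr.shape[0]).astype(str).astype(object)


def fit_pca(traits: pd.DataFrame | np.ndarray, standardize: bool = True) -> PCModel:
    """Fit PCA on a subjects x K trait matrix.

    With ``standardize`` (the default) columns are scaled to unit variance
    before the eigendecomposition, since embedding dimensions carry arbitrary
    units. Eigenvector signs are fixed so each component's
    largest-magnitude loading is positive, making the decomposition
    deterministic across numerical backends.
    """
    x, names, _ = _as_matrix(traits)
    n, k = x.shape
    if n <= k:
        raise ValidationError(f"need more subjects ({n}) than trait columns ({k})")
    if np.isnan(x).any():
        raise ValidationError("trait matrix contains missing values")
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValidationError(
            f"zero-variance trait columns: {[names[i] for i in zero]}"
        )
    scale = sd if standardize else None
    xc = (x - center) / sd if standardize else x - center
    # SVD of the centered matrix == eigendecomposition of the sample covariance
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt.T
    eigvals = s**2 / (n - 1)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(k)] < 0
    loadings[:, flip] *= -1
    total = eigvals.sum()
    return PCModel(
        center=center,
        scale=scale,
        loadings=loadings,
        variance_explained=eigvals / total,
        column_names=names,
    )


def transform(traits: pd.DataFrame | np.ndarray, model: PCModel, m: int | None = None) -> PCMatrix:
    """Project traits onto the first ``m`` components of a fitted model."""
    x, names, ids = _as_matrix(traits)
    if x.shape[1] != model.k:
        raise ValidationError(
            f"trait matrix has {x.shape[1]} columns; model expects {model.k}"
        )
    if isinstance(traits, pd.DataFrame) and names != model.column_names:
        raise ValidationError("trait column names do not match the fitted model")
    m = model.k if m is None else m
    if not 1 <= m <= model.k:
        raise ValidationError(f"m must be in [1, {model.k}], got {m}")
    xc = x - model.center
    if model.scale is not None:
        xc = xc / model.scale
    scores = xc @ model.loadings[:, :m]
    return PCMatrix(subject_ids=ids, components=scores, m=m)


def select_m(model: PCModel, policy: str = "fixed", value: float = 5) -> int:
    """Choose how many leading components to carry into GWAS.

    ``fixed`` returns ``value`` (clipped nowhere — out of range is an error);
    ``variance_threshold`` returns the smallest m whose cumulative variance
    explained reaches ``value``.
    """
    if policy == "fixed":
        m = int(value)
        if not 1 <= m <= model.k:
            raise ValidationError(f"fixed m must be in [1, {model.k}], got {value}")
        return m
    if policy == "variance_threshold":
        if not 0 < value <= 1:
            raise ValidationError(f"variance threshold must be in (0, 1], got {value}")
        cum = np.cumsum(model.variance_explained)
        return int(np.searchsorted(cum, value - 1e-12) + 1)
    raise ValueError(f"unknown policy {policy!r}")
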