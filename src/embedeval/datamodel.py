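"""Core data containers and genotype/tabular I/O.

Dosages are stored as a dense ``float64`` matrix of alternate-allele counts in
``[0, 2]`` with ``NaN`` marking missing genotypes.  Variant metadata travels
with the dosage matrix in a :class:`pandas.DataFrame` so that downstream
summary statistics can always report chromosome, position and alleles.

Conventions
-----------
* Genomic positions are 1-based, as in PLINK ``.bim`` files.
* Chromosomes are stored as strings (admits ``"X"``); sorting is
  lexicographic on ``(chrom, pos_bp)``.
* The effect allele is PLINK allele 1 (A1); all betas and PRS weights are
  reported with respect to it.
* Subject order is canonicalized to sorted subject id.
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("embedeval")

VARIANT_COLUMNS = ["chrom", "pos_bp", "id", "effect_allele", "other_allele"]

_PLINK_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes, SNP-major: 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Dosage counts copies of A1 (the effect allele).
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """An in-memory container violates one of its invariants."""


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; ``verbose`` enables DEBUG."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    subject_ids
        Unique, opaque string identifiers, one per row of ``dosages``.
    dosages
        ``(n_subjects, n_variants)`` float matrix of effect-allele counts in
        ``[0, 2]``; ``NaN`` marks missing calls.
    variants
        DataFrame with columns ``chrom, pos_bp, id, effect_allele,
        other_allele`` (and optionally ``exclude`` set by imputation), sorted
        by ``(chrom, pos_bp)``.
    """

    subject_ids: np.ndarray
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n, v = self.dosages.shape
        if n != len(self.subject_ids):
            raise ValidationError(
                f"dosages have {n} rows but {len(self.subject_ids)} subject ids"
            )
        if v != len(self.variants):
            raise ValidationError(
                f"dosages have {v} columns but {len(self.variants)} variant records"
            )
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate variant ids: {dups[:10]}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValidationError("dosage values outside [0, 2]")
        key = list(zip(self.variants["chrom"], self.variants["pos_bp"]))
        if key != sorted(key):
            raise ValidationError("variants not sorted by (chrom, pos_bp)")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def subset_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.subject_ids)}
        idx = np.array([order[s] for s in ids], dtype=int)
        return GenotypeMatrix(np.asarray(ids, dtype=object), self.dosages[idx], self.variants.copy())


def _sorted_variant_order(variants: pd.DataFrame) -> np.ndarray:
    return np.lexsort((variants["pos_bp"].to_numpy(), variants["chrom"].to_numpy()))


def make_genotype_matrix(
    subject_ids: Sequence[str], dosages: np.ndarray, variants: pd.DataFrame
) -> GenotypeMatrix:
    """Construct a :class:`GenotypeMatrix`, sorting variants by position."""
    order = _sorted_variant_order(variants)
    return GenotypeMatrix(
        np.asarray(subject_ids, dtype=object),
        np.asarray(dosages, dtype=np.float64)[:, order],
        variants.iloc[order].reset_index(drop=True),
    )


@dataclass
class SubjectTable:
    """One row per subject of named numeric columns (traits, covariates, labels)."""

    data: pd.DataFrame  # index = subject_id

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate subject ids in table")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate column names in table")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=object)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubjectTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="subject_id")


@dataclass
class CohortBundle:
    """Genotypes plus subject tables restricted to one identically ordered cohort."""

    genotypes: GenotypeMatrix
    tables: list[SubjectTable]
    role: str = "discovery"  # discovery | evaluation
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = list(self.genotypes.subject_ids)
        for i, t in enumerate(self.tables):
            if list(t.subject_ids) != ref:
                raise ValidationError(f"table {i} subject order differs from genotypes")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.genotypes.subject_ids

    def table(self, *columns: str) -> pd.DataFrame:
        """Concatenate the named columns from whichever member tables hold them."""
        out = {}
        for col in columns:
            for t in self.tables:
                if col in t.data.columns:
                    out[col] = t.data[col].to_numpy()
                    break
            else:
                raise KeyError(f"column {col!r} not found in any bundle table")
        return pd.DataFrame(out, index=self.genotypes.subject_ids)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "plink1") -> GenotypeMatrix:
    """Read genotypes from a PLINK 1 triple (``path`` = prefix) or a TSV file."""
    if format == "plink1":
        return read_plink1(path)
    if format == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_plink1(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset ``prefix``.bed/.bim/.fam (SNP-major)."""
    prefix = Path(prefix)
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FormatError(f"missing PLINK file: {f}")

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    subject_ids = fam_df[1].to_numpy(dtype=object)
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    variants = pd.DataFrame(
        {
            "chrom": bim_df["chrom"],
            "pos_bp": bim_df["pos_bp"].astype(int),
            "id": bim_df["id"],
            "effect_allele": bim_df["a1"],
            "other_allele": bim_df["a2"],
        }
    )
    if variants["id"].duplicated().any():
        raise ValidationError(f"duplicate variant ids in {bim}")

    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise FormatError(f"bad magic bytes in {bed}: not a SNP-major PLINK 1 .bed")
    body = raw[3:]
    n, v = len(subject_ids), len(variants)
    bytes_per_variant = (n + 3) // 4
    if body.size != bytes_per_variant * v:
        raise FormatError(
            f"{bed}: expected {bytes_per_variant * v} data bytes for "
            f"{n} subjects x {v} variants, found {body.size}"
        )
    body = body.reshape(v, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((v, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T  # subjects x variants
    return make_genotype_matrix(subject_ids, dosages, variants)


def write_plink1(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK 1 .bed/.bim/.fam triple; dosages must be in {0, 1, 2, NaN}."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    d = g.dosages
    hard = np.where(np.isnan(d), -1, d)
    if not np.all(np.isin(hard, [-1, 0, 1, 2])):
        raise ValidationError("PLINK 1 stores hard calls only; fractional dosage found")
    # dosage -> 2-bit code
    code_of = {2.0: 0, -1.0: 1, 1.0: 2, 0.0: 3}
    codes = np.vectorize(code_of.get)(hard).astype(np.uint8).T  # variants x subjects
    n, v = g.n_subjects, g.n_variants
    bytes_per_variant = (n + 3) // 4
    padded = np.ones((v, bytes_per_variant * 4), dtype=np.uint8) * 0  # pad with 0b00
    padded[:, :n] = codes
    packed = np.zeros((v, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos_bp": g.variants["pos_bp"],
            "a1": g.variants["effect_allele"],
            "a2": g.variants["other_allele"],
        }
    )
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.subject_ids,
            "iid": g.subject_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV: header row of variant ids, first column subject ids.

    Variant metadata is synthesized (single chromosome, positions in column
    order) since the toy format carries none.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    dosages = df.to_numpy(dtype=np.float64)
    vals = dosages[~np.isnan(dosages)]
    if vals.size and (vals.min() < 0 or vals.max() > 2):
        raise ValidationError(f"{path}: dosage values outside [0, 2]")
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos_bp": np.arange(1, df.shape[1] + 1),
            "id": [str(c) for c in df.columns],
            "effect_allele": "A",
            "other_allele": "B",
        }
    )
    if variants["id"].duplicated().any():
        raise ValidationError(f"duplicate variant ids in {path}")
    return make_genotype_matrix(df.index.to_numpy(dtype=object), dosages, variants)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.dosages, index=g.subject_ids, columns=g.variant_ids)
    df.to_csv(path, sep="\t", index_label="subject_id")


# ---------------------------------------------------------------------------
# Cohort alignment and imputation
# ---------------------------------------------------------------------------


def align_cohort(
    genotypes: GenotypeMatrix, *tables: SubjectTable, role: str = "discovery"
) -> CohortBundle:
    """Restrict genotypes and tables to their common subjects, sorted by id.

    Idempotent: aligning an already aligned bundle's members is a no-op.
    """
    shared = set(genotypes.subject_ids)
    for t in tables:
        shared &= set(t.subject_ids)
    if not shared:
        raise ValidationError("no shared subject ids across inputs")
    order = sorted(shared)
    dropped = {"genotypes": genotypes.n_subjects - len(order)}
    for i, t in enumerate(tables):
        dropped[f"table_{i}"] = len(t.subject_ids) - len(order)
    for name, k in dropped.items():
        if k:
            logger.info("align_cohort: dropped %d subjects from %s", k, name)
    aligned_tables = [SubjectTable(t.data.loc[order]) for t in tables]
    return CohortBundle(genotypes.subset_subjects(order), aligned_tables, role, dropped)


def impute_missing_dosages(g: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing dosages per variant.

    All-missing or zero-variance variants are flagged in an ``exclude`` column
    of the variant table (all-missing columns are set to dosage 0).
    """
    d = g.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN columns
        means = np.nanmean(d, axis=0)
    all_missing = np.isnan(means)
    means = np.where(all_missing, 0.0, means)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.take(means, np.nonzero(nan_mask)[1])
    variance = d.var(axis=0)
    exclude = all_missing | (variance == 0)
    if exclude.any():
        logger.info("impute: flagged %d degenerate variants", int(exclude.sum()))
    variants = g.variants.copy()
    variants["exclude"] = exclude
    return GenotypeMatrix(g.subject_ids.copy(), d, variants)
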