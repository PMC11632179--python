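"""Multivariate chi-square combination, LD clumping, heritability metrics.

Because the PC phenotypes are orthogonal on the discovery cohort, their
per-variant Wald statistics are asymptotically independent standard normals
under the null, so the combined statistic

    T = sum_{k=1..m} z_k^2

is referred to a central chi-square with m degrees of freedom. T tests
whether a variant is associated with *any* of the m components.

Clumping is the usual greedy index-variant selection: visit significant
variants in ascending p-value order; each unpruned one becomes an index and
prunes every unpruned variant within the window whose dosage R-squared with
it exceeds the threshold. Heritability is then summarized by the number of
genome-wide significant (p <= 5e-8) clump indices and the mean/median T among
them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeMatrix, ValidationError, logger
from .gwas import UnivariateSummaryStats

GWS_P = 5e-8


@dataclass
class MultivariateSummaryStats:
    """Per-variant combined statistic T with its chi-square_m p-value."""

    m: int
    table: pd.DataFrame  # id, chrom, pos_bp, T, p

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "#CHROM": self.table["chrom"],
                "POS": self.table["pos_bp"],
                "ID": self.table["id"],
                "T_STAT": self.table["T"],
                "DF": self.m,
                "P": self.table["p"],
            }
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MultivariateSummaryStats":
        df = pd.read_csv(path, sep="\t", dtype={"#CHROM": str, "ID": str})
        table = pd.DataFrame(
            {
                "id": df["ID"],
                "chrom": df["#CHROM"],
                "pos_bp": df["POS"].astype(int),
                "T": df["T_STAT"].astype(float),
                "p": df["P"].astype(float),
            }
        )
        return cls(m=int(df["DF"].iloc[0]), table=table)


@dataclass
class LDMap:
    """Sparse within-window R-squared map: ``neighbors[id] -> {other_id: r2}``."""

    window_kb: float
    neighbors: dict = field(default_factory=dict)
    zero_variance: set = field(default_factory=set)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.neighbors.get(a, {}).get(b, 0.0)


@dataclass
class ClumpedSet:
    """Greedy clumping result: retained index variants plus prune assignments."""

    index_variants: list[str]
    assignments: dict  # pruned id -> index id

    def to_tsv(self, stats: "MultivariateSummaryStats | UnivariateSummaryStats", path: str | Path) -> None:
        t = stats.table.set_index("id")
        members: dict[str, list[str]] = {ix: [] for ix in self.index_variants}
        for pruned, ix in self.assignments.items():
            members[ix].append(pruned)
        rows = []
        for ix in self.index_variants:
            rows.append(
                {
                    "CHROM": t.loc[ix, "chrom"],
                    "POS": t.loc[ix, "pos_bp"],
                    "ID": ix,
                    "P": t.loc[ix, "p"],
                    "SP2": ",".join(sorted(members[ix])) or "NONE",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class HeritabilityReport:
    """GWS hit count and mean/median combined chi-square at clumped indices."""

    n_gws_hits: int
    mean_chi2: float | None
    median_chi2: float | None
    gws_threshold: float = GWS_P

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def combine_stats(per_pc: list[UnivariateSummaryStats]) -> MultivariateSummaryStats:
    """Combine per-PC Wald z statistics into T = sum z_k^2 ~ chi-square_m."""
    if not per_pc:
        raise ValidationError("need at least one per-PC summary table")
    ref = per_pc[0].table
    ref_ids = list(ref["id"])
    for s in per_pc[1:]:
        ids = list(s.table["id"])
        if set(ids) != set(ref_ids):
            diff = sorted(set(ids) ^ set(ref_ids))
            raise ValidationError(f"variant sets differ between PCs: {diff[:10]}")
    m = len(per_pc)
    t = np.zeros(len(ref_ids))
    for s in per_pc:
        z = s.table.set_index("id").loc[ref_ids, "z"].to_numpy(dtype=float)
        t += z**2
    p = np.clip(stats.chi2.sf(t, df=m), np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {
            "id": ref["id"].to_numpy(),
            "chrom": ref["chrom"].to_numpy(),
            "pos_bp": ref["pos_bp"].to_numpy(),
            "T": t,
            "p": p,
        }
    )
    return MultivariateSummaryStats(m=m, table=table)


def pairwise_r2(genotypes: GenotypeMatrix, window_kb: float = 250.0) -> LDMap:
    """Squared Pearson correlation for same-chromosome variant pairs within a window.

    Zero-variance variants get R-squared 0 with every partner and are flagged.
    Requires imputed (no-missing) dosages.
    """
    d = genotypes.dosages
    if np.isnan(d).any():
        raise ValidationError("genotypes contain missing dosages; impute first")
    ids = genotypes.variant_ids
    chroms = genotypes.variants["chrom"].to_numpy()
    pos = genotypes.variants["pos_bp"].to_numpy()
    sd = d.std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.info("pairwise_r2: %d zero-variance variants (R2 set to 0)", int(zero.sum()))
    std = (d - d.mean(axis=0)) / np.where(zero, 1.0, sd)
    std[:, zero] = 0.0
    n = d.shape[0]
    window_bp = window_kb * 1000.0
    neighbors: dict[str, dict[str, float]] = {}
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]  # position-sorted already
        cpos = pos[idx]
        hi = 0
        for a_i, i in enumerate(idx):
            while hi < len(idx) and cpos[hi] - cpos[a_i] <= window_bp:
                hi += 1
            js = idx[a_i + 1 : hi]
            if js.size == 0:
                continue
            r = std[:, i] @ std[:, js] / n
            r2 = r**2
            for j, val in zip(js, r2):
                val = 0.0 if (zero[i] or zero[j]) else float(val)
                neighbors.setdefault(ids[i], {})[ids[j]] = val
                neighbors.setdefault(ids[j], {})[ids[i]] = val
    return LDMap(
        window_kb=window_kb,
        neighbors=neighbors,
        zero_variance=set(ids[zero]),
    )


def clump(
    stats_in: MultivariateSummaryStats | UnivariateSummaryStats,
    r2_map: LDMap,
    p1: float = GWS_P,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> ClumpedSet:
    """Greedy LD clumping of significant variants.

    Within each LD region only the variant with the lowest p-value is
    retained; ties in p are broken by (chrom, pos_bp, id) for determinism.
    """
    if window_kb > r2_map.window_kb:
        raise ValidationError(
            f"clump window {window_kb} kb exceeds the R2 map window {r2_map.window_kb} kb"
        )
    t = stats_in.table
    pos_of = dict(zip(t["id"], zip(t["chrom"], t["pos_bp"])))
    sig = t[t["p"] <= p1]
    order = sig.sort_values(["p", "chrom", "pos_bp", "id"], kind="mergesort")
    window_bp = window_kb * 1000.0
    pruned: dict[str, str] = {}
    index_variants: list[str] = []
    for vid in order["id"]:
        if vid in pruned:
            continue
        index_variants.append(vid)
        chrom, pos = pos_of[vid]
        for other, r2 in r2_map.neighbors.get(vid, {}).items():
            if other in pruned or other == vid or other in index_variants:
                continue
            ochrom, opos = pos_of.get(other, (None, None))
            if ochrom != chrom or abs(opos - pos) > window_bp:
                continue
            if r2 > r2_threshold:
                pruned[other] = vid
    return ClumpedSet(index_variants=index_variants, assignments=pruned)


def heritability_metrics(
    stats_in: MultivariateSummaryStats,
    clumps: ClumpedSet,
    gws_p: float = GWS_P,
) -> HeritabilityReport:
    """Count GWS clump indices and summarize their combined chi-square."""
    t = stats_in.table.set_index("id")
    hits = [v for v in clumps.index_variants if t.loc[v, "p"] <= gws_p]
    if not hits:
        return HeritabilityReport(n_gws_hits=0, mean_chi2=None, median_chi2=None, gws_threshold=gws_p)
    chi2 = t.loc[hits, "T"].to_numpy(dtype=float)
    return HeritabilityReport(
        n_gws_hits=len(hits),
        mean_chi2=float(chi2.mean()),
        median_chi2=float(np.median(chi2)),
        gws_threshold=gws_p,
    )
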