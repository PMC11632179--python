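import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embedeval import (
    LDMap,
    PCMatrix,
    UnivariateSummaryStats,
    ValidationError,
    batch_gwas,
    clump,
    combine_stats,
    heritability_metrics,
    pairwise_r2,
)
from embedeval.multivariate import MultivariateSummaryStats

from conftest import toy_genotypes


def stats_from_z(z_by_pc):
    """Build per-PC summary tables directly from z values (one variant per entry)."""
    out = []
    v = len(z_by_pc[0])
    for k, zs in enumerate(z_by_pc):
        table = pd.DataFrame(
            {
                "id": [f"var{j:05d}" for j in range(v)],
                "chrom": "1",
                "pos_bp": 1 + np.arange(v) * 10**6,
                "effect_allele": "A",
                "n": 100,
                "beta": np.asarray(zs, dtype=float),
                "se": 1.0,
                "z": np.asarray(zs, dtype=float),
                "p": 2 * stats.norm.sf(np.abs(zs)),
                "zero_var": False,
            }
        )
        out.append(UnivariateSummaryStats(pc_index=k + 1, table=table))
    return out


def mv_from_p(p_values, positions=None, chrom="1"):
    v = len(p_values)
    pos = positions if positions is not None else 1 + np.arange(v) * 10**6
    table = pd.DataFrame(
        {
            "id": [f"var{j:05d}" for j in range(v)],
            "chrom": chrom,
            "pos_bp": pos,
            "T": stats.chi2.isf(np.asarray(p_values, dtype=float), 2),
            "p": np.asarray(p_values, dtype=float),
        }
    )
    return MultivariateSummaryStats(m=2, table=table)


class TestCombineStats:
    def test_null_point(self):
        mv = combine_stats(stats_from_z([[0.0], [0.0]]))
        assert mv.table["T"].iloc[0] == 0.0
        assert mv.table["p"].iloc[0] == 1.0
        assert mv.m == 2

    def test_single_pc_chi2_matches_squared_normal(self):
        mv = combine_stats(stats_from_z([[3.0]]))
        assert mv.table["T"].iloc[0] == pytest.approx(9.0)
        assert mv.table["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(3.0), rel=1e-12)
        assert mv.table["p"].iloc[0] == pytest.approx(0.0027, abs=1e-4)

    def test_m1_p_equals_two_sided_normal_p(self, rng):
        z = rng.normal(size=200) * 2
        per_pc = stats_from_z([z])
        mv = combine_stats(per_pc)
        np.testing.assert_allclose(mv.table["p"], per_pc[0].table["p"], rtol=1e-10)

    def test_t_is_sum_of_squares(self, rng):
        z1, z2, z3 = (rng.normal(size=50) for _ in range(3))
        mv = combine_stats(stats_from_z([z1, z2, z3]))
        np.testing.assert_allclose(mv.table["T"], z1**2 + z2**2 + z3**2, atol=1e-10)
        assert mv.m == 3
        # p monotone decreasing in T
        order = np.argsort(mv.table["T"].to_numpy())
        assert (np.diff(mv.table["p"].to_numpy()[order]) <= 0).all()

    def test_variant_set_mismatch_error(self):
        a, b = stats_from_z([[1.0, 2.0], [1.0, 2.0]])
        b.table.loc[1, "id"] = "varXXXXX"
        with pytest.raises(ValidationError, match="varXXXXX"):
            combine_stats([a, b])


class TestPairwiseR2:
    def test_duplicate_column_r2_is_one(self, rng):
        col = rng.binomial(2, 0.4, size=50).astype(float)
        g = toy_genotypes(np.column_stack([col, col]), spacing=1000)
        ld = pairwise_r2(g, window_kb=250)
        assert ld.r2("var00000", "var00001") == pytest.approx(1.0)

    def test_windowing_excludes_distant_pairs(self, rng):
        g = toy_genotypes(rng.binomial(2, 0.4, size=(50, 2)), spacing=1_000_000)
        ld = pairwise_r2(g, window_kb=250)
        assert ld.neighbors == {}
        assert ld.r2("var00000", "var00001") == 0.0

    def test_independent_variants_mean_r2_near_1_over_n(self, rng):
        n, v = 10_000, 500
        maf = rng.uniform(0.1, 0.5, size=v)
        g = toy_genotypes(rng.binomial(2, maf, size=(n, v)), spacing=100)
        ld = pairwise_r2(g, window_kb=10**6)
        vals = [r2 for d in ld.neighbors.values() for r2 in d.values()]
        assert len(vals) == v * (v - 1)  # stored symmetrically
        assert np.mean(vals) == pytest.approx(1 / n, rel=0.15)

    def test_zero_variance_variant_r2_zero(self, rng):
        a = rng.binomial(2, 0.4, size=40).astype(float)
        g = toy_genotypes(np.column_stack([a, np.ones(40)]), spacing=1000)
        ld = pairwise_r2(g, window_kb=250)
        assert ld.r2("var00000", "var00001") == 0.0
        assert "var00001" in ld.zero_variance


def clump_oracle(stats_table, r2_lookup, p1, r2_threshold, window_bp):
    """Exhaustive reference: repeatedly take the best remaining significant variant."""
    remaining = {
        row["id"]: (row["chrom"], row["pos_bp"], row["p"])
        for _, row in stats_table.iterrows()
    }
    index, assigned = [], {}
    while True:
        sig = [
            (p, chrom, pos, vid)
            for vid, (chrom, pos, p) in remaining.items()
            if p <= p1
        ]
        if not sig:
            break
        _, chrom, pos, best = min(sig)
        index.append(best)
        del remaining[best]
        for vid in list(remaining):
            vchrom, vpos, _ = remaining[vid]
            if vchrom == chrom and abs(vpos - pos) <= window_bp:
                if r2_lookup(best, vid) > r2_threshold:
                    assigned[vid] = best
                    del remaining[vid]
    return index, assigned


class TestClump:
    def test_three_variant_example(self):
        mv = mv_from_p([1e-10, 1e-9, 1e-8], positions=[100, 200, 300])
        ld = LDMap(window_kb=250, neighbors={
            "var00000": {"var00001": 0.8, "var00002": 0.0},
            "var00001": {"var00000": 0.8, "var00002": 0.0},
            "var00002": {"var00000": 0.0, "var00001": 0.0},
        })
        out = clump(mv, ld, p1=5e-8, r2_threshold=0.1, window_kb=250)
        assert out.index_variants == ["var00000", "var00002"]
        assert out.assignments == {"var00001": "var00000"}

    def test_single_significant_variant(self):
        mv = mv_from_p([1e-10, 0.5])
        out = clump(mv, LDMap(window_kb=250), p1=5e-8, r2_threshold=0.1, window_kb=250)
        assert out.index_variants == ["var00000"]

    def test_no_ld_means_no_pruning(self):
        mv = mv_from_p([1e-10, 1e-9, 1e-12])
        out = clump(mv, LDMap(window_kb=250), p1=5e-8, r2_threshold=0.1, window_kb=250)
        assert sorted(out.index_variants) == ["var00000", "var00001", "var00002"]
        assert out.assignments == {}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        """Greedy clumping equals the brute-force reference on correlated blocks."""
        rng = np.random.default_rng(seed)
        n, v = 400, 150
        base = rng.binomial(2, 0.4, size=(n, v)).astype(float)
        # induce LD: copy a neighbour with noise for a third of variants
        for j in range(1, v, 3):
            flip = rng.random(n) < 0.1
            base[:, j] = np.where(flip, rng.binomial(2, 0.4, size=n), base[:, j - 1])
        g = toy_genotypes(base, spacing=50_000)
        ld = pairwise_r2(g, window_kb=250)
        p = 10 ** (-rng.uniform(0, 12, size=v))
        mv = mv_from_p(p, positions=g.variants["pos_bp"].to_numpy())
        out = clump(mv, ld, p1=1e-4, r2_threshold=0.1, window_kb=250)
        oracle_index, oracle_assigned = clump_oracle(
            mv.table, ld.r2, 1e-4, 0.1, 250_000
        )
        assert out.index_variants == oracle_index
        assert out.assignments == oracle_assigned

    @pytest.mark.parametrize("seed", [0, 1])
    def test_raising_r2_threshold_never_loses_indices(self, seed):
        rng = np.random.default_rng(seed)
        n, v = 300, 80
        base = rng.binomial(2, 0.4, size=(n, v)).astype(float)
        for j in range(1, v, 2):
            flip = rng.random(n) < 0.3
            base[:, j] = np.where(flip, rng.binomial(2, 0.4, size=n), base[:, j - 1])
        g = toy_genotypes(base, spacing=50_000)
        ld = pairwise_r2(g, window_kb=250)
        mv = mv_from_p(10 ** (-rng.uniform(0, 10, size=v)), positions=g.variants["pos_bp"].to_numpy())
        counts = [
            len(clump(mv, ld, p1=1e-3, r2_threshold=thr, window_kb=250).index_variants)
            for thr in (0.05, 0.1, 0.3, 0.5, 0.9)
        ]
        assert counts == sorted(counts)

    def test_output_invariants_hold(self, rng):
        n, v = 300, 60
        base = rng.binomial(2, 0.4, size=(n, v)).astype(float)
        for j in range(1, v, 2):
            flip = rng.random(n) < 0.2
            base[:, j] = np.where(flip, rng.binomial(2, 0.4, size=n), base[:, j - 1])
        g = toy_genotypes(base, spacing=50_000)
        ld = pairwise_r2(g, window_kb=250)
        mv = mv_from_p(10 ** (-rng.uniform(0, 10, size=v)), positions=g.variants["pos_bp"].to_numpy())
        out = clump(mv, ld, p1=1e-3, r2_threshold=0.1, window_kb=250)
        p_of = dict(zip(mv.table["id"], mv.table["p"]))
        # no two index variants in high LD
        for i, a in enumerate(out.index_variants):
            for b in out.index_variants[i + 1 :]:
                assert ld.r2(a, b) <= 0.1
        # every pruned variant is in LD with, and no stronger than, its index
        for pruned, ix in out.assignments.items():
            assert ld.r2(pruned, ix) > 0.1
            assert p_of[pruned] >= p_of[ix]


class TestHeritabilityMetrics:
    def _clumps(self, ids):
        from embedeval import ClumpedSet

        return ClumpedSet(index_variants=list(ids), assignments={})

    def test_singleton(self):
        mv = mv_from_p([1e-9])
        mv.table.loc[0, "T"] = 40.0
        rep = heritability_metrics(mv, self._clumps(["var00000"]))
        assert (rep.n_gws_hits, rep.mean_chi2, rep.median_chi2) == (1, 40.0, 40.0)

    def test_no_hits_reports_null(self):
        mv = mv_from_p([1e-4, 0.2])
        rep = heritability_metrics(mv, self._clumps([]))
        assert rep.n_gws_hits == 0
        assert rep.mean_chi2 is None and rep.median_chi2 is None

    def test_mean_and_median(self):
        mv = mv_from_p([1e-9, 1e-10, 1e-11])
        mv.table["T"] = [30.0, 50.0, 100.0]
        rep = heritability_metrics(mv, self._clumps(mv.table["id"]))
        assert rep.n_gws_hits == 3
        assert rep.mean_chi2 == pytest.approx(60.0)
        assert rep.median_chi2 == pytest.approx(50.0)


class TestNullCalibration:
    def test_combined_statistic_matches_chi2_m(self, rng):
        """Noise PCs on independent genotypes: T ~ chi-square_2, 5% level calibrated."""
        n, v, m = 800, 2500, 2
        g = toy_genotypes(rng.binomial(2, rng.uniform(0.1, 0.5, size=v), size=(n, v)))
        pcs = PCMatrix(g.subject_ids, rng.normal(size=(n, m)), m)
        mv = combine_stats(batch_gwas(pcs, g))
        t_vals = mv.table["T"].to_numpy()
        assert stats.kstest(t_vals, stats.chi2(df=m).cdf).pvalue > 0.01
        # empirical type-I error at alpha=0.05 within the 99% binomial interval
        rate = float(np.mean(mv.table["p"] <= 0.05))
        half = 2.576 * np.sqrt(0.05 * 0.95 / v)
        assert 0.05 - half <= rate <= 0.05 + half
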