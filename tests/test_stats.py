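import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sstats

import speechtrf as st
from speechtrf.stats import AdjacencyGraph, PermutationConfig


class TestDependentTMap:
    def test_equal_conditions_zero(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 3, 7))
        t = st.dependent_t_map(a, a.copy())
        np.testing.assert_array_equal(t, 0.0)

    def test_constant_difference_infinite(self):
        a = np.zeros((4, 2, 3))
        b = a - 1.0  # constant difference of +1, zero within-pair variance
        t = st.dependent_t_map(a, b)
        assert np.all(np.isposinf(t))

    def test_matches_direct_formula_on_toy_set(self):
        # 5-subject toy set, oracle = mean(d) * sqrt(n) / sd(d)
        a = np.array([3.1, 2.9, 3.5, 3.0, 3.3])
        b = np.array([2.8, 3.0, 3.1, 2.7, 3.0])
        d = a - b
        oracle = d.mean() * np.sqrt(5) / d.std(ddof=1)
        t = st.dependent_t_map(a.reshape(5, 1, 1), b.reshape(5, 1, 1))
        assert t[0, 0] == pytest.approx(oracle)
        scipy_t = sstats.ttest_rel(a, b).statistic
        assert t[0, 0] == pytest.approx(scipy_t)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            st.dependent_t_map(np.zeros((3, 2, 2)), np.zeros((3, 2, 3)))


class TestAdjacency:
    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            AdjacencyGraph(labels=("a", "b"),
                           neighbors={"a": frozenset({"b"}),
                                      "b": frozenset()})

    def test_self_neighbor_rejected(self):
        with pytest.raises(ValueError):
            AdjacencyGraph(labels=("a",),
                           neighbors={"a": frozenset({"a"})})

    def test_distance_threshold_graph(self):
        from speechtrf.montage import build_adjacency, default_montage
        adj = build_adjacency(default_montage())
        g = AdjacencyGraph.from_sets(adj)  # validates symmetry/no-self
        assert all(len(v) > 0 for v in g.neighbors.values())


class TestClusterPermutationTest:
    def test_identical_conditions_no_clusters(self, chain_adjacency):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((8, 8, 10))
        res = st.cluster_permutation_test(
            a, a.copy(), chain_adjacency,
            PermutationConfig(n_permutations=100, min_neighbors=1))
        assert res.clusters == ()

    def test_relabel_symmetry(self, chain_adjacency):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((8, 8, 10))
        b = rng.standard_normal((8, 8, 10))
        cfg = PermutationConfig(n_permutations=200, min_neighbors=1, seed=3)
        res_ab = st.cluster_permutation_test(a, b, chain_adjacency, cfg)
        res_ba = st.cluster_permutation_test(b, a, chain_adjacency, cfg)
        masses_ab = sorted(c.mass for c in res_ab.clusters)
        masses_ba = sorted(-c.mass for c in res_ba.clusters)
        np.testing.assert_allclose(masses_ab, masses_ba, atol=1e-10)

    def test_channel_reorder_invariance(self, chain_adjacency):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((8, 8, 10))
        b = rng.standard_normal((8, 8, 10))
        cfg = PermutationConfig(n_permutations=150, min_neighbors=1, seed=5)
        names = tuple(f"c{i}" for i in range(8))
        res1 = st.cluster_permutation_test(a, b, chain_adjacency, cfg,
                                           channel_names=names)
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        res2 = st.cluster_permutation_test(
            a[:, perm, :], b[:, perm, :], chain_adjacency, cfg,
            channel_names=tuple(names[i] for i in perm))
        m1 = sorted(round(c.mass, 9) for c in res1.clusters)
        m2 = sorted(round(c.mass, 9) for c in res2.clusters)
        assert m1 == m2

    def test_injected_effect_detected(self, chain_adjacency):
        # power check: strong offset on neighboring channels, N1-range lags
        rng = np.random.default_rng(6)
        cfg = PermutationConfig(n_permutations=200, min_neighbors=1, seed=7)
        detected = 0
        runs = 10
        for _ in range(runs):
            a = rng.standard_normal((10, 8, 12))
            b = rng.standard_normal((10, 8, 12))
            a[:, 2:5, 4:8] += 2.5
            res = st.cluster_permutation_test(a, b, chain_adjacency, cfg)
            sig = [c for c in res.clusters if c.significant]
            ok = any(set(range(4, 8)) & set(l for _, l in c.members)
                     for c in sig)
            detected += ok
        assert detected >= 9

    def test_exact_enumeration_warning_tiny_n(self, chain_adjacency):
        a = np.zeros((2, 8, 5))
        b = np.ones((2, 8, 5)) * 0.1
        with pytest.warns(UserWarning, match="sign patterns"):
            st.cluster_permutation_test(
                a, b, chain_adjacency,
                PermutationConfig(n_permutations=100, min_neighbors=1))

    def test_min_neighbors_blocks_isolated_channel(self):
        # two disconnected channels: min_neighbors=1 removes all samples
        adj = AdjacencyGraph(labels=("a", "b"),
                             neighbors={"a": frozenset(), "b": frozenset()})
        rng = np.random.default_rng(8)
        a = rng.standard_normal((10, 2, 6)) + 3.0
        b = rng.standard_normal((10, 2, 6))
        res = st.cluster_permutation_test(
            a, b, adj, PermutationConfig(n_permutations=100,
                                         min_neighbors=1))
        assert res.clusters == ()


class TestBonferroni:
    def test_correction_arithmetic(self):
        # raw p 0.01 * 64 = 0.64 (ns); raw p 0.0005 * 64 = 0.032 (sig)
        assert min(1.0, 0.01 * 64) == pytest.approx(0.64)
        assert min(1.0, 0.0005 * 64) == pytest.approx(0.032)

    def test_matches_direct_oracle_on_toy_channels(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((12, 4))
        b = rng.standard_normal((12, 4)) + np.array([0, 0, 0, 2.0])
        t, p_corr, sig = st.bonferroni_channel_tests(a, b)
        for ch in range(4):
            res = sstats.ttest_rel(a[:, ch], b[:, ch])
            assert t[ch] == pytest.approx(res.statistic)
            assert p_corr[ch] == pytest.approx(min(1.0, res.pvalue * 4))
        assert sig[3] and not sig[0]

    def test_explicit_n(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((8, 2))
        b = a + 0.01 * rng.standard_normal((8, 2))
        _, p4, _ = st.bonferroni_channel_tests(a, b, N=4)
        _, p1, _ = st.bonferroni_channel_tests(a, b, N=1)
        np.testing.assert_allclose(np.minimum(1.0, p1 * 4), p4)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            st.bonferroni_channel_tests(np.zeros((3, 2)), np.ones((3, 2)),
                                        N=0)


class TestChanceLevel:
    def test_printed_value_n30(self):
        level = st.empirical_chance_level(st.ChanceLevelSpec(30, 2, 0.05))
        assert level == pytest.approx(100 * 19 / 30)
        assert round(level, 2) == 63.33

    def test_n1_gives_100(self):
        assert st.empirical_chance_level(
            st.ChanceLevelSpec(1, 2, 0.05)) == 100.0

    def test_n10_gives_80(self):
        # exact CDF enumeration: CDF(7)=0.9453 < 0.95 <= CDF(8)=0.9893
        assert st.empirical_chance_level(
            st.ChanceLevelSpec(10, 2, 0.05)) == 80.0

    def test_matches_cdf_enumeration(self):
        for n in range(5, 101, 5):
            spec = st.ChanceLevelSpec(n, 2, 0.05)
            level = st.empirical_chance_level(spec)
            ks = np.arange(n + 1)
            cdf = sstats.binom.cdf(ks, n, 0.5)
            k_oracle = ks[cdf >= 0.95][0]
            assert level == pytest.approx(100 * k_oracle / n)

    def test_decreasing_trend_in_n(self):
        # the threshold is NOT strictly non-increasing (integer-k ripple,
        # e.g. 80% at n=5 vs 83.33% at n=6); assert the decreasing trend
        # and the 50% asymptote instead
        levels = np.array([
            st.empirical_chance_level(st.ChanceLevelSpec(n, 2, 0.05))
            for n in range(5, 101)])
        assert np.mean(levels[:10]) > np.mean(levels[-10:])
        assert np.all(levels > 50.0)
        assert levels[-1] < 60.0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            st.ChanceLevelSpec(0, 2, 0.05)
        with pytest.raises(ValueError):
            st.ChanceLevelSpec(10, 1, 0.05)


class TestPairedBehavioralTest:
    def test_equal_inputs(self):
        a = np.array([70.0, 80.0, 90.0])
        t, p = st.paired_behavioral_test(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_symmetric_differences_zero_t(self):
        t, _ = st.paired_behavioral_test(np.array([1.0, -1.0]),
                                         np.array([0.0, 0.0]))
        assert t == 0.0

    def test_matches_direct_formula_six_subjects(self):
        a = np.array([77.5, 80.0, 72.5, 85.0, 90.0, 75.0])
        b = np.array([82.5, 85.0, 80.0, 87.5, 92.5, 85.0])
        d = a - b
        oracle_t = d.mean() * np.sqrt(6) / d.std(ddof=1)
        oracle_p = 2 * sstats.t.sf(abs(oracle_t), df=5)
        t, p = st.paired_behavioral_test(a, b)
        assert t == pytest.approx(oracle_t)
        assert p == pytest.approx(oracle_p)
        res = sstats.ttest_rel(a, b)
        assert t == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_degenerate_sentinel(self):
        t, p = st.paired_behavioral_test(np.array([2.0, 3.0]),
                                         np.array([1.0, 2.0]))
        assert np.isposinf(t) and p == 0.0


@settings(max_examples=20, deadline=None)
@given(hst.integers(min_value=2, max_value=12),
       hst.integers(min_value=0, max_value=2**31 - 1))
def test_t_map_antisymmetry_property(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, 2, 3))
    b = rng.standard_normal((n, 2, 3))
    np.testing.assert_allclose(st.dependent_t_map(a, b),
                               -st.dependent_t_map(b, a), atol=1e-10)
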