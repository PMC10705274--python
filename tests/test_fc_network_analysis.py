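"""Graph metrics against brute-force and networkx oracles, and NBS."""

import itertools

import networkx as nx
import numpy as np
import pytest

import mesoplast as mp
from mesoplast.fc_network_analysis import (
    DEFAULT_THRESHOLDS,
    proportional_threshold,
)


def brute_efficiency(adj):
    """Floyd-Warshall + inverse-distance average, written independently."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1)) if n > 1 else 0.0


def brute_transitivity(adj):
    """Exhaustive triple enumeration of Newman's formula."""
    n = adj.shape[0]
    num = 0.0
    den = 0.0
    for i in range(n):
        k = adj[i].sum()
        den += k * (k - 1)
        t = 0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and h != j:
                    t += adj[i, j] * adj[i, h] * adj[j, h]
        num += t  # = 2 * t_i
    return num / den if den > 0 else 0.0


class TestWorkedGraphValues:
    def test_complete_graph_efficiency_is_one(self):
        k4 = np.ones((4, 4)) - np.eye(4)
        assert mp.global_efficiency(k4) == pytest.approx(1.0)

    def test_empty_graph_efficiency_is_zero(self):
        assert mp.global_efficiency(np.zeros((5, 5))) == 0.0

    def test_path_graph_efficiency_five_sixths(self):
        p3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert mp.global_efficiency(p3) == pytest.approx(5.0 / 6.0)

    def test_triangle_transitivity_is_one(self):
        k3 = np.ones((3, 3)) - np.eye(3)
        assert mp.transitivity(k3) == pytest.approx(1.0)

    def test_four_cycle_transitivity_is_zero(self):
        c4 = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            c4[i, j] = c4[j, i] = 1.0
        assert mp.transitivity(c4) == 0.0

    def test_k4_minus_edge_transitivity_three_quarters(self):
        g = np.ones((4, 4)) - np.eye(4)
        g[0, 1] = g[1, 0] = 0.0
        assert mp.transitivity(g) == pytest.approx(0.75)


class TestOracleEquivalence:
    def test_all_graphs_up_to_5_nodes_match_brute_force_and_networkx(self):
        n = 5
        pairs = list(itertools.combinations(range(n), 2))
        for bits in range(2 ** len(pairs)):
            adj = np.zeros((n, n))
            for b, (i, j) in enumerate(pairs):
                if bits >> b & 1:
                    adj[i, j] = adj[j, i] = 1.0
            assert mp.global_efficiency(adj) == pytest.approx(
                brute_efficiency(adj), abs=1e-12
            )
            assert mp.transitivity(adj) == pytest.approx(
                brute_transitivity(adj), abs=1e-12
            )

    def test_random_graphs_match_networkx(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            adj = (rng.random((n, n)) < 0.3).astype(float)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            g = nx.from_numpy_array(adj)
            assert mp.global_efficiency(adj) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12
            )
            assert mp.transitivity(adj) == pytest.approx(
                nx.transitivity(g), abs=1e-12
            )

    def test_efficiency_monotone_under_edge_addition(self, rng):
        n = 12
        for _ in range(10):
            adj = np.zeros((n, n))
            prev = 0.0
            pairs = list(itertools.combinations(range(n), 2))
            rng.shuffle(pairs)
            for i, j in pairs[:40]:
                adj[i, j] = adj[j, i] = 1.0
                cur = mp.global_efficiency(adj)
                assert cur >= prev - 1e-12
                prev = cur


class TestProportionalThreshold:
    def test_top_edge_only(self):
        fc = np.eye(3)
        fc[0, 1] = fc[1, 0] = 0.9
        fc[0, 2] = fc[2, 0] = 0.5
        fc[1, 2] = fc[2, 1] = 0.1
        g = proportional_threshold(fc, 1 / 3)
        assert g.adjacency[0, 1] == 1.0
        assert g.adjacency.sum() == 2.0  # one edge, symmetric

    def test_near_one_keeps_all_edges(self, random_fc):
        g = proportional_threshold(random_fc, 0.999)
        off = ~np.eye(90, dtype=bool)
        assert g.adjacency[off].mean() > 0.99

    def test_ten_percent_of_90_nodes_keeps_400_or_401_edges(self, random_fc):
        g = proportional_threshold(random_fc, 0.10)
        assert g.adjacency.sum() / 2 == round(0.10 * 4005)

    def test_out_of_range_p_rejected(self, random_fc):
        for p in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                proportional_threshold(random_fc, p)

    def test_invariant_under_joint_permutation(self, random_fc, rng):
        perm = rng.permutation(90)
        v = random_fc.values
        vp = v[np.ix_(perm, perm)]
        for p in (0.05, 0.18):
            a = proportional_threshold(v, p).adjacency
            b = proportional_threshold(vp, p).adjacency
            np.testing.assert_array_equal(a[np.ix_(perm, perm)], b)


class TestAucAndSummaries:
    def test_constant_metric_gives_rectangle_area(self, random_fc):
        auc = mp.metric_auc(random_fc, lambda g: 2.0)
        assert auc == pytest.approx(2.0 * 0.13)

    def test_trapezoid_matches_fine_riemann_on_smooth_metric(self, random_fc):
        vals = [
            mp.global_efficiency(proportional_threshold(random_fc, p))
            for p in DEFAULT_THRESHOLDS
        ]
        riemann = np.trapezoid(vals, DEFAULT_THRESHOLDS)
        assert mp.metric_auc(random_fc, mp.global_efficiency) == pytest.approx(
            riemann, abs=1e-9
        )

    def test_mean_fc_arithmetic(self):
        fc = np.eye(3)
        fc[0, 1] = fc[1, 0] = 0.2
        fc[0, 2] = fc[2, 0] = 0.4
        fc[1, 2] = fc[2, 1] = 0.6
        assert mp.mean_fc(fc) == pytest.approx(0.4)
        assert mp.mean_fc(fc, {0, 1, 2}) == pytest.approx(0.4)

    def test_masked_mean_matches_double_loop(self, random_fc, atlas):
        mask = mp.select_mask(atlas, {"parietal", "occipital"})
        idx = sorted(mask)
        acc, cnt = 0.0, 0
        for i in idx:
            for j in idx:
                if i != j:
                    acc += random_fc.values[i, j]
                    cnt += 1
        assert mp.mean_fc(random_fc, mask) == pytest.approx(acc / cnt, abs=1e-12)

    def test_singleton_mask_rejected(self, random_fc):
        with pytest.raises(ValueError):
            mp.mean_fc(random_fc, {3})

    def test_nodal_strength_sums_offdiagonals(self, random_fc):
        s = mp.nodal_strength(random_fc)
        v = random_fc.values.copy()
        np.fill_diagonal(v, 0.0)
        np.testing.assert_allclose(s, v.sum(axis=0), atol=1e-12)  # symmetry


class TestNBS:
    @staticmethod
    def _null_groups(rng, n_sub=10, n=15):
        mats = rng.standard_normal((2 * n_sub, n, n)) * 0.1 + 0.3
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        for m in mats:
            np.fill_diagonal(m, 1.0)
        return list(mats[:n_sub]), list(mats[n_sub:])

    def test_identical_groups_give_p_one(self, rng):
        a, _ = self._null_groups(rng)
        res = mp.nbs(a, list(a), t_threshold=3.0, n_perm=50, seed=1)
        assert res.max_component_size == 0
        assert res.p_value == 1.0

    def test_planted_component_recovered(self, rng):
        a, b = self._null_groups(rng, n_sub=31, n=20)
        planted = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7),
                   (7, 8), (8, 9), (9, 10)]
        sd = np.std([m[0, 1] for m in a + b])
        for m in a:
            for i, j in planted:
                m[i, j] += 2 * sd
                m[j, i] = m[i, j]
        res = mp.nbs(a, b, t_threshold=3.0, n_perm=200, seed=2)
        found = {tuple(sorted(e)) for e in res.component_edges}
        assert len(found & set(planted)) >= 8
        assert res.p_value < 0.01

    def test_invariant_to_subject_order(self, rng):
        a, b = self._null_groups(rng)
        r1 = mp.nbs(a, b, t_threshold=2.0, n_perm=50, seed=3)
        r2 = mp.nbs(a[::-1], b[::-1], t_threshold=2.0, n_perm=50, seed=3)
        assert r1.max_component_size == r2.max_component_size
        assert r1.p_value == r2.p_value

    def test_type_i_error_calibrated(self):
        # reduced-size null calibration; binomial 95% band around 0.05
        local = np.random.default_rng(999)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            a, b = self._null_groups(local, n_sub=8, n=12)
            res = mp.nbs(a, b, t_threshold=2.0, n_perm=99, seed=rep)
            rejections += res.p_value <= 0.05
        assert 0.01 <= rejections / n_rep <= 0.09

    def test_degenerate_edge_warns_and_scores_zero(self, rng):
        # edge (0,1) is constant and nonzero in every subject
        a, b = self._null_groups(rng, n_sub=4, n=4)
        for m in a + b:
            m[0, 1] = m[1, 0] = 0.5
        with pytest.warns(RuntimeWarning):
            res = mp.nbs(a, b, t_threshold=1.0, n_perm=20, seed=0)
        assert res.t_matrix[0, 1] == 0.0
        assert np.isfinite(res.t_matrix).all()
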