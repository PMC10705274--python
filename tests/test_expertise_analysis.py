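"""Greedy covariate search, connectome conversion, similarity, term maps."""

import itertools

import numpy as np
import pytest

import mesoplast as mp
from mesoplast.expertise_analysis import TermMap


def brute_force_greedy(mats, cov, edges):
    """Per-step exhaustive oracle for the greedy forward selection."""
    cov = np.asarray(cov, float)
    cols = {e: np.array([m[e[0], e[1]] for m in mats]) for e in edges}
    chosen, best_r = [], -np.inf
    while len(chosen) < len(edges):
        cands = []
        for e in sorted(set(edges) - set(chosen)):
            vals = np.mean([cols[c] for c in chosen + [e]], axis=0)
            r = np.corrcoef(cov, vals)[0, 1]
            cands.append((round(r, 12), e))
        r_new, e_new = max(cands, key=lambda t: (t[0], [-x for x in t[1]]))
        # max on (r, edge) with lexicographically smallest edge on ties
        r_new, e_new = sorted(cands, key=lambda t: (-t[0], t[1]))[0]
        if r_new <= best_r + 1e-12:
            break
        chosen.append(e_new)
        best_r = r_new
    return chosen, best_r


@pytest.fixture()
def greedy_problem(rng):
    n_sub, n = 12, 8
    mats = []
    for _ in range(n_sub):
        m = rng.standard_normal((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        mats.append(m)
    edges = list(itertools.combinations(range(5), 2))  # 10 masked edges
    return mats, edges


class TestGreedy:
    def test_single_edge_mask_returns_it(self, greedy_problem, rng):
        mats, _ = greedy_problem
        cov = rng.standard_normal(len(mats))
        res = mp.greedy_subnetwork(mats, cov, [(0, 3)])
        assert res.edges == [(0, 3)]
        assert len(res.r_trace) == 1

    def test_constructed_optimum_reaches_r_one(self, greedy_problem):
        mats, edges = greedy_problem
        e1, e2 = (0, 1), (2, 3)
        cov = np.array([(m[e1] + m[e2]) / 2 for m in mats])
        res = mp.greedy_subnetwork(mats, cov, edges)
        assert res.r_final >= 1.0 - 1e-9

    def test_matches_per_step_brute_force_oracle(self, greedy_problem, rng):
        mats, edges = greedy_problem
        for trial in range(5):
            cov = rng.standard_normal(len(mats))
            res = mp.greedy_subnetwork(mats, cov, edges)
            oracle_edges, oracle_r = brute_force_greedy(mats, cov, edges)
            assert res.edges == oracle_edges
            assert res.r_final == pytest.approx(oracle_r, abs=1e-9)

    def test_trace_is_nondecreasing_and_final_is_max(self, greedy_problem, rng):
        mats, edges = greedy_problem
        cov = rng.standard_normal(len(mats))
        res = mp.greedy_subnetwork(mats, cov, edges)
        assert np.all(np.diff(res.r_trace) > 0)
        assert res.r_final == max(res.r_trace)

    def test_zero_variance_covariate_rejected(self, greedy_problem):
        mats, edges = greedy_problem
        with pytest.raises(ValueError):
            mp.greedy_subnetwork(mats, np.ones(len(mats)), edges)


class TestTransferConnections:
    @pytest.fixture()
    def group_means(self, small_dataset):
        from mesoplast.model_fitting import group_average_sc

        _, ds = small_dataset
        return (
            group_average_sc(ds.subjects, "VGP"),
            group_average_sc(ds.subjects, "NVGP"),
        )

    def test_fraction_zero_is_identity(self, group_means):
        expert, nonexpert = group_means
        out = mp.transfer_connections(expert, nonexpert, 0.0)
        np.testing.assert_array_equal(out.weights, nonexpert.weights)

    def test_fraction_one_moves_closer_to_expert(self, group_means):
        expert, nonexpert = group_means
        out = mp.transfer_connections(expert, nonexpert, 1.0)
        d0 = np.linalg.norm(nonexpert.weights - expert.weights)
        d1 = np.linalg.norm(out.weights - expert.weights)
        assert d1 < d0

    def test_mean_strength_preserved(self, group_means):
        expert, nonexpert = group_means
        for frac in (0.25, 0.5, 1.0):
            out = mp.transfer_connections(expert, nonexpert, frac)
            assert out.weights.mean() == pytest.approx(
                nonexpert.weights.mean(), abs=1e-9
            )

    def test_symmetry_and_nonnegativity_preserved(self, group_means):
        expert, nonexpert = group_means
        out = mp.transfer_connections(expert, nonexpert, 0.5)
        np.testing.assert_allclose(out.weights, out.weights.T, atol=1e-12)
        assert out.weights.min() >= 0.0

    def test_ranking_tie_breaks_lexicographically(self):
        expert = np.zeros((4, 4))
        nonexpert = np.zeros((4, 4))
        # two eligible edges with the same difference
        for i, j in [(0, 3), (1, 2)]:
            expert[i, j] = expert[j, i] = 0.5
        expert[0, 1] = expert[1, 0] = 0.9  # keeps the matrix nonzero
        nonexpert[0, 1] = nonexpert[1, 0] = 0.9
        ranked = mp.ranked_transfer_edges(expert, nonexpert)
        assert ranked[:2] == [(0, 3), (1, 2)]

    def test_invalid_fraction_rejected(self, group_means):
        expert, nonexpert = group_means
        with pytest.raises(ValueError):
            mp.transfer_connections(expert, nonexpert, 1.5)


class TestSCSimilarity:
    def test_self_similarity_one(self, rng):
        w = rng.random((10, 10))
        w = w + w.T
        assert mp.sc_similarity(w, w) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        w = rng.random((10, 10))
        w = w + w.T
        assert mp.sc_similarity(w, 2 * w) == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        a = rng.random((10, 10))
        a = a + a.T
        b = rng.random((10, 10))
        b = b + b.T
        iu = np.triu_indices(10, 1)
        x, y = a[iu], b[iu]
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert mp.sc_similarity(a, b) == pytest.approx(manual, abs=1e-12)


class TestTermMaps:
    def test_identical_map_correlates_to_one(self, rng):
        diff = rng.standard_normal(90)
        table = mp.term_map_correlation(diff, [TermMap("self", diff.copy())])
        assert table.loc[0, "r"] == pytest.approx(1.0)

    def test_negated_map_correlates_to_minus_one(self, rng):
        diff = rng.standard_normal(90)
        table = mp.term_map_correlation(diff, [TermMap("anti", -diff)])
        assert table.loc[0, "r"] == pytest.approx(-1.0)

    def test_constant_map_skipped_with_warning(self, rng):
        diff = rng.standard_normal(90)
        with pytest.warns(RuntimeWarning):
            table = mp.term_map_correlation(
                diff, [TermMap("flat", np.ones(90)), TermMap("ok", diff)]
            )
        assert list(table["term"]) == ["ok"]

    def test_null_maps_rarely_survive_fdr(self, rng):
        # 89 independent null maps: BH at q < 0.05 yields ~0 discoveries
        discoveries = 0
        for _ in range(50):
            diff = rng.standard_normal(90)
            maps = [TermMap(f"t{k}", rng.standard_normal(90)) for k in range(89)]
            table = mp.term_map_correlation(diff, maps)
            discoveries += int((table["q"] < 0.05).sum())
        assert discoveries / 50 < 0.3

    def test_sorted_by_r_descending(self, rng):
        diff = rng.standard_normal(90)
        maps = [TermMap(f"t{k}", rng.standard_normal(90)) for k in range(10)]
        table = mp.term_map_correlation(diff, maps)
        assert np.all(np.diff(table["r"]) <= 0)
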