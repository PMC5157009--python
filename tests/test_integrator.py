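"""Design matrix construction and correlation-maximizing integration."""

import numpy as np
import pytest

from unicorn import (
    SearchParams,
    TrainingSet,
    WeightedNetwork,
    build_design_matrix,
    fit_integration,
    integrate_networks,
    merge_levels,
    search_discretization,
)
from unicorn.integrator import DesignMatrix, fit_integration_monotone


def _training(sims):
    return TrainingSet(pairs=list(sims), similarity=sims, t_s=0.3)


def _discretize(net, training, k=6, seed=0):
    weights = {p: net.weights[p] for p in training.pairs if p in net.weights}
    dmap = search_discretization(
        weights, training, SearchParams(k=k, max_iterations=300, restarts=2, seed=seed)
    )
    return merge_levels(dmap)


class TestDesignMatrix:
    def _simple(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        sims = {p: s for p, s in zip(pairs, (0.2, 0.5, 0.9))}
        tr = _training(sims)
        net = WeightedNetwork({pairs[0]: 1.0, pairs[1]: 2.0, pairs[2]: 3.0}, name="n1")
        return tr, net

    def test_one_nonzero_per_row_per_network(self):
        tr, net = self._simple()
        dm = build_design_matrix([(net, _discretize(net, tr))], tr)
        assert dm.matrix.shape[0] == 3
        nz = (dm.matrix != 0).sum(axis=1)
        assert np.all(nz == 1)

    def test_missing_edge_gives_zero_block(self):
        tr, net1 = self._simple()
        net2 = WeightedNetwork({("a", "b"): 5.0, ("c", "d"): 6.0}, name="n2")
        d1, d2 = _discretize(net1, tr), _discretize(net2, tr, seed=1)
        dm = build_design_matrix([(net1, d1), (net2, d2)], tr)
        row_ef = dm.pairs.index(("e", "f"))
        assert np.all(dm.matrix[row_ef, dm.column_slice(1)] == 0)
        assert np.any(dm.matrix[row_ef, dm.column_slice(0)] != 0)

    def test_column_count_is_sum_of_levels(self):
        tr, net1 = self._simple()
        net2 = WeightedNetwork(
            {("a", "b"): 5.0, ("c", "d"): 6.0, ("e", "f"): 6.0}, name="n2"
        )
        d1, d2 = _discretize(net1, tr), _discretize(net2, tr, seed=1)
        dm = build_design_matrix([(net1, d1), (net2, d2)], tr)
        assert dm.n_columns == d1.n_levels + d2.n_levels

    def test_entry_is_discretized_weight(self):
        tr, net = self._simple()
        dmap = _discretize(net, tr)
        dm = build_design_matrix([(net, dmap)], tr)
        lw = dmap.level_weight
        for i, p in enumerate(dm.pairs):
            l = dmap.level_of[p]
            assert dm.matrix[i, l] == pytest.approx(lw[l])


def _random_design(n=30, k=6, seed=0):
    # columns carry a constant value (the level's representative weight,
    # increasing across levels), as build_design_matrix produces
    rng = np.random.default_rng(seed)
    level_weight = np.sort(rng.uniform(0.1, 1.0, k))
    m = np.zeros((n, k))
    for i in range(n):
        j = rng.integers(k)
        m[i, j] = level_weight[j]
    s = m @ rng.uniform(0, 1, k) + rng.normal(0, 0.2, n)
    return DesignMatrix(matrix=m, pairs=[(f"a{i}", f"b{i}") for i in range(n)],
                        network_names=["net"], level_counts=[k]), s


class TestFitIntegration:
    def test_single_column_recovers_abs_pcc(self):
        rng = np.random.default_rng(1)
        col = rng.random(20)
        s = -2 * col + rng.normal(0, 0.1, 20)
        dm = DesignMatrix(matrix=col[:, None], pairs=[("a", f"b{i}") for i in range(20)],
                          network_names=["n"], level_counts=[1])
        coef = fit_integration(dm, s)
        assert abs(abs(float(coef.a[0])) - 1.0) < 1e-12
        assert coef.achieved_pcc == pytest.approx(abs(np.corrcoef(col, s)[0, 1]))

    def test_perfect_linear_combination_gives_one(self):
        dm, _ = _random_design(seed=2)
        truth = np.linspace(0.1, 1.0, dm.n_columns)
        s = dm.matrix @ truth
        coef = fit_integration(dm, s)
        assert coef.achieved_pcc == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_and_beats_random_directions(self):
        dm, s = _random_design(n=30, k=6, seed=3)
        coef = fit_integration(dm, s)
        mc = dm.matrix - dm.matrix.mean(axis=0)
        a_ls, *_ = np.linalg.lstsq(mc, s - s.mean(), rcond=None)
        pcc_ls = abs(np.corrcoef(dm.matrix @ a_ls, s)[0, 1])
        assert coef.achieved_pcc == pytest.approx(pcc_ls, abs=1e-8)
        rng = np.random.default_rng(99)
        for _ in range(1000):
            b = rng.normal(size=dm.n_columns)
            b /= np.linalg.norm(b)
            pcc_b = abs(np.corrcoef(dm.matrix @ b, s)[0, 1])
            assert coef.achieved_pcc >= pcc_b - 1e-10

    def test_unit_norm_and_nonnegative_pcc(self):
        dm, s = _random_design(seed=4)
        coef = fit_integration(dm, s)
        assert np.linalg.norm(coef.a) == pytest.approx(1.0)
        assert 0 <= coef.achieved_pcc <= 1

    def test_invariance_to_column_scale_and_s_shift(self):
        dm, s = _random_design(seed=5)
        base = fit_integration(dm, s).achieved_pcc
        m2 = dm.matrix.copy()
        m2[:, 2] *= 7.5
        dm2 = DesignMatrix(matrix=m2, pairs=dm.pairs,
                           network_names=dm.network_names, level_counts=dm.level_counts)
        assert fit_integration(dm2, s + 3.0).achieved_pcc == pytest.approx(base, abs=1e-9)

    def test_beats_equal_weight_summation(self):
        dm, s = _random_design(seed=6)
        coef = fit_integration(dm, s)
        ones = np.ones(dm.n_columns) / np.sqrt(dm.n_columns)
        pcc_sum = abs(np.corrcoef(dm.matrix @ ones, s)[0, 1])
        assert coef.achieved_pcc >= pcc_sum - 1e-12

    def test_constant_similarity_errors(self):
        dm, _ = _random_design(seed=7)
        with pytest.raises(ValueError, match="constant"):
            fit_integration(dm, np.ones(dm.matrix.shape[0]))

    def test_all_zero_design_errors(self):
        dm = DesignMatrix(matrix=np.zeros((5, 2)), pairs=[("a", f"b{i}") for i in range(5)],
                          network_names=["n"], level_counts=[2])
        with pytest.raises(ValueError, match="zero"):
            fit_integration(dm, np.arange(5.0))


class TestMonotoneFit:
    def test_products_nondecreasing_within_network(self):
        dm, s = _random_design(n=40, k=8, seed=8)
        coef = fit_integration_monotone(dm, s)
        col_vals = dm.matrix.max(axis=0)
        products = coef.a * col_vals
        assert np.all(np.diff(products) >= -1e-12)

    def test_bounded_by_unconstrained_fit(self):
        dm, s = _random_design(n=40, k=8, seed=9)
        pcc_iso = fit_integration_monotone(dm, s).achieved_pcc
        pcc_ols = fit_integration(dm, s).achieved_pcc
        assert pcc_iso <= pcc_ols + 1e-9
        assert pcc_iso > 0

    def test_recovers_monotone_truth(self):
        # when the true level effects are increasing, both solvers agree
        dm, _ = _random_design(n=200, k=5, seed=10)
        truth = np.array([0.1, 0.2, 0.4, 0.7, 1.0])
        s = dm.matrix @ truth
        pcc_iso = fit_integration_monotone(dm, s).achieved_pcc
        assert pcc_iso == pytest.approx(1.0, abs=1e-6)


class TestIntegrateNetworks:
    def test_hand_computed_combination(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        sims = {p: s for p, s in zip(pairs, (0.1, 0.5, 0.9))}
        tr = _training(sims)
        n1 = WeightedNetwork({pairs[0]: 1.0, pairs[1]: 2.0, pairs[2]: 3.0}, name="n1")
        n2 = WeightedNetwork({pairs[1]: 5.0, pairs[2]: 9.0}, name="n2")
        d1, d2 = _discretize(n1, tr), _discretize(n2, tr, seed=1)
        dm = build_design_matrix([(n1, d1), (n2, d2)], tr)
        s = np.array([sims[p] for p in dm.pairs])
        coef = fit_integration(dm, s)
        out = integrate_networks([(n1, d1), (n2, d2)], coef, rescale=False)
        for p in pairs:
            expected = 0.0
            off = 0
            for net, dmap in [(n1, d1), (n2, d2)]:
                if p in net.weights:
                    l = dmap.level_of[p]
                    expected += coef.a[off + l] * dmap.level_weight[l]
                off += dmap.n_levels
            assert out.weights[p] == pytest.approx(expected)

    def test_pair_in_one_network_only(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        tr = _training({pairs[0]: 0.2, pairs[1]: 0.8, pairs[2]: 0.5})
        n1 = WeightedNetwork({pairs[0]: 1.0, pairs[1]: 2.0}, name="n1")
        n2 = WeightedNetwork({pairs[1]: 3.0, pairs[2]: 4.0}, name="n2")
        d1, d2 = _discretize(n1, tr), _discretize(n2, tr, seed=1)
        dm = build_design_matrix([(n1, d1), (n2, d2)], tr)
        coef = fit_integration(dm, np.array([tr.similarity[p] for p in dm.pairs]))
        out = integrate_networks([(n1, d1), (n2, d2)], coef, rescale=False)
        # (a, b) has an edge in n1 only: its weight comes from n1 alone
        l = d1.level_of[pairs[0]]
        assert out.weights[pairs[0]] == pytest.approx(coef.a[l] * d1.level_weight[l])

    def test_training_edges_correlate_at_achieved_pcc(self):
        rng = np.random.default_rng(12)
        pairs = [(f"a{i}", f"b{i}") for i in range(40)]
        sims = {p: float(rng.random()) for p in pairs}
        tr = _training(sims)
        net = WeightedNetwork(
            {p: sims[p] + rng.normal(0, 0.3) for p in pairs}, name="n"
        )
        dmap = _discretize(net, tr, k=20)
        dm = build_design_matrix([(net, dmap)], tr)
        s = np.array([sims[p] for p in dm.pairs])
        coef = fit_integration(dm, s)
        out = integrate_networks([(net, dmap)], coef, rescale=True)
        w = np.array([out.weights.get(p, 0.0) for p in dm.pairs])
        assert abs(np.corrcoef(w, s)[0, 1]) == pytest.approx(
            coef.achieved_pcc, abs=1e-8
        )
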