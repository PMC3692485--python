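import numpy as np
import pandas as pd
import pytest

from histonet import pcnet, synth
from histonet.pcnet import (
    BICTrace,
    bic_trace,
    build_network,
    network_bic,
    pairwise_partial_correlations,
    partial_correlation_residual,
    partial_correlation_triple,
    permutation_null,
    select_threshold,
)


def random_data(m, v, seed, colnames=None):
    rng = np.random.default_rng(seed)
    cols = colnames or [f"v{i}" for i in range(v)]
    return pd.DataFrame(rng.standard_normal((m, v)), columns=cols)


class TestTripleFormula:
    def test_forced_zero(self):
        assert partial_correlation_triple(0.4, 0.8, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_identical_variables(self):
        for c in (0.0, 0.3, -0.7):
            assert partial_correlation_triple(1.0, c, c) == pytest.approx(1.0)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(ValueError, match="perfectly correlated"):
            partial_correlation_triple(0.5, 1.0, 0.5)

    def test_matches_residual_regression_on_toy_data(self):
        data = random_data(5, 3, seed=2)
        corr = data.corr()
        closed = partial_correlation_triple(
            corr.iloc[0, 1], corr.iloc[0, 2], corr.iloc[1, 2]
        )
        residual = partial_correlation_residual(data, "v0", "v1")
        assert closed == pytest.approx(residual, abs=1e-10)


class TestPairwisePcor:
    def test_matches_residual_route_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(30, 200))
            v = int(rng.integers(3, 8))
            data = random_data(m, v, seed=int(rng.integers(1 << 30)))
            pc = pairwise_partial_correlations(data)
            a, b = data.columns[0], data.columns[-1]
            assert pc.loc[a, b] == pytest.approx(
                partial_correlation_residual(data, a, b), abs=1e-8
            )

    def test_symmetric_unit_diagonal_bounded(self):
        pc = pairwise_partial_correlations(random_data(100, 5, seed=3))
        arr = pc.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1)
        assert (np.abs(arr) <= 1 + 1e-12).all()

    def test_independent_columns_give_small_pcors(self):
        for seed in range(1, 11):
            data = random_data(2000, 6, seed=seed)
            pc = pairwise_partial_correlations(data).to_numpy()
            off = pc[np.triu_indices(6, k=1)]
            assert np.abs(off).max() < 4 / np.sqrt(2000)

    def test_converges_to_declared_precision(self):
        data, truth = synth.make_feature_scenario(
            n_features=6, m=20000, seed=4, feature_edges=[(0, 1, 0.5), (2, 3, 0.3)]
        )
        est = pairwise_partial_correlations(data)
        true = truth.true_pcor()
        err = (est - true).abs().to_numpy()
        assert err[np.triu_indices(6, k=1)].max() < 0.05

    def test_collinear_columns_rejected(self):
        data = random_data(100, 4, seed=5)
        data["v3"] = data["v0"] * 0.9999999 + 1e-9 * data["v1"]
        with pytest.raises(ValueError, match="near-singular|collinear"):
            pairwise_partial_correlations(data)

    def test_more_variables_than_rows_rejected(self):
        with pytest.raises(ValueError, match="more rows"):
            pairwise_partial_correlations(random_data(5, 6, seed=6))


class TestNetworkBIC:
    def test_empty_network_is_sum_of_intercept_models(self):
        data = random_data(200, 4, seed=7)
        total = network_bic(data, [])
        m = len(data)
        expected = 0.0
        for c in data.columns:
            y = data[c].to_numpy()
            rss = float(np.sum((y - y.mean()) ** 2))
            expected += m * (np.log(2 * np.pi * rss / m) + 1) + np.log(m)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_true_edge_lowers_score(self):
        for seed in range(1, 11):
            data, _ = synth.make_feature_scenario(
                n_features=4, m=2000, seed=seed, feature_edges=[(0, 1, 0.5)]
            )
            a, b = data.columns[0], data.columns[1]
            assert network_bic(data, [(a, b)]) < network_bic(data, [])

    def test_noise_edge_usually_raises_score(self):
        worse = 0
        for seed in range(1, 11):
            data = random_data(2000, 4, seed=seed)
            worse += network_bic(data, [("v0", "v1")]) > network_bic(data, [])
        assert worse >= 8

    def test_trace_consistent_with_direct_scoring(self):
        data, _ = synth.make_feature_scenario(
            n_features=5, m=500, seed=8, feature_edges=[(0, 1, 0.4), (1, 2, 0.3)]
        )
        trace = bic_trace(data)
        for i in (0, 3, len(trace.pairs)):
            assert trace.bics[i] == pytest.approx(
                network_bic(data, trace.pairs[:i]), rel=1e-10
            )


class TestThresholdSelection:
    @staticmethod
    def toy_trace(diffs, pcors):
        bics = np.concatenate([[1000.0], 1000.0 - np.cumsum(diffs)])
        pairs = [(f"a{i}", f"b{i}") for i in range(len(pcors))]
        return BICTrace(pairs=pairs, pcors=np.array(pcors), bics=bics, diffs=np.array(diffs, dtype=float))

    def test_forced_decision_rule(self):
        trace = self.toy_trace([100, 50, 30, 15, 5], [0.9, 0.8, 0.7, 0.6, 0.5])
        threshold = select_threshold(trace, fraction=0.2)
        assert trace.selected_index == 3
        assert threshold == pytest.approx(0.7)

    def test_all_equal_differences_keep_everything(self):
        trace = self.toy_trace([10, 10, 10], [0.5, 0.4, 0.3])
        select_threshold(trace)
        assert trace.selected_index == 3

    def test_late_large_step_is_not_truncated_by_earlier_dip(self):
        trace = self.toy_trace([100, 5, 60], [0.8, 0.6, 0.4])
        select_threshold(trace)
        assert trace.selected_index == 3

    def test_single_pair_kept_with_warning(self):
        trace = self.toy_trace([40], [0.6])
        with pytest.warns(UserWarning):
            assert select_threshold(trace) == pytest.approx(0.6)

    def test_ggm_edges_recovered(self, ggm_scenario):
        data, truth = ggm_scenario
        trace = bic_trace(data)
        select_threshold(trace)
        selected = {frozenset(p) for p in trace.selected_edges()}
        assert selected == truth.true_edges()


class TestPermutationNull:
    def test_marginals_preserved_exactly(self):
        data = random_data(50, 3, seed=9)
        rng = np.random.default_rng(0)
        perm = pcnet._derangement_rows(50, rng)
        assert sorted(data.iloc[perm, 0]) == sorted(data.iloc[:, 0])

    def test_no_fixed_points_even_for_two_rows(self):
        rng = np.random.default_rng(0)
        assert list(pcnet._derangement_rows(2, rng)) == [1, 0]
        for _ in range(5):
            p = pcnet._derangement_rows(17, rng)
            assert not np.any(p == np.arange(17))

    def test_independent_data_gives_small_z_for_typical_pcor(self):
        data = random_data(500, 5, seed=10)
        typical = float(
            np.abs(
                pairwise_partial_correlations(data).to_numpy()[np.triu_indices(5, 1)]
            ).mean()
        )
        res = permutation_null(data, threshold=typical, n_perm=30, seed=1)
        assert abs(res.z) < 3

    def test_structured_data_threshold_clears_null(self, ggm_scenario):
        data, _ = ggm_scenario
        trace = bic_trace(data)
        threshold = select_threshold(trace)
        res = permutation_null(data, threshold, n_perm=50, seed=2)
        assert res.max_abs_null < threshold
        assert res.z > 5


class TestBuildNetwork:
    def test_threshold_above_everything_gives_empty_network(self):
        pc = pairwise_partial_correlations(random_data(200, 4, seed=11))
        net = build_network(pc, threshold=0.99)
        assert net.graph.number_of_edges() == 0

    def test_normalized_weights_peak_at_one(self, ggm_scenario):
        data, _ = ggm_scenario
        pc = pairwise_partial_correlations(data)
        net = build_network(pc, threshold=0.2)
        assert net.edges["normalized_pcor"].abs().max() == pytest.approx(1.0)

    def test_driver_scenario_wires_exon_to_its_parents(self):
        data, truth = synth.scenario("small", m=5000, seed=6)
        pc = pairwise_partial_correlations(data)
        trace = bic_trace(data, pc)
        threshold = select_threshold(trace)
        net = build_network(pc, threshold, response="exon_expr")
        assert set(net.neighbors("exon_expr")) == {"H3K36me3", "H4K20me1", "gene_expr"}

    def test_response_node_attributes_normalized(self, small_scenario):
        data, _ = small_scenario
        pc = pairwise_partial_correlations(data)
        net = build_network(pc, threshold=0.15, response="exon_expr")
        vals = [
            net.graph.nodes[n]["normalized_pcor_with_response"]
            for n in net.graph.nodes
            if n != "exon_expr"
        ]
        assert max(abs(v) for v in vals) == pytest.approx(1.0)
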