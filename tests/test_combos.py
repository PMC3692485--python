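import numpy as np
import pandas as pd
import pytest

from histonet import combos, pcnet, synth
from histonet.combos import (
    bin_summary,
    cluster_matrix_export,
    median_bins,
    network_combination_tests,
    stepwise_bic_by_pcor,
)


def additive_frame(m=2000, seed=0, synergy=0.0, noise=0.5):
    rng = np.random.default_rng(seed)
    f1 = rng.standard_normal(m)
    f2 = rng.standard_normal(m)
    y = f1 + f2 + synergy * f1 * f2 + noise * rng.standard_normal(m)
    idx = [f"e{i}" for i in range(m)]
    return (
        pd.Series(f1, index=idx, name="f1"),
        pd.Series(f2, index=idx, name="f2"),
        pd.Series(y, index=idx, name="y"),
    )


class TestMedianBins:
    def test_forced_assignment(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], name="a")
        b = pd.Series([4.0, 3.0, 2.0, 1.0], name="b")
        bins = median_bins(a, b)
        assert list(bins.labels) == ["LH", "LH", "HL", "HL"]

    def test_value_at_median_is_low(self):
        a = pd.Series([1.0, 2.0, 2.0, 3.0], name="a")
        b = pd.Series([5.0, 6.0, 6.0, 7.0], name="b")
        bins = median_bins(a, b)
        # rows sitting exactly at the median fall to Low
        assert list(bins.labels) == ["LL", "LL", "LL", "HH"]

    def test_constant_feature_rejected(self):
        a = pd.Series([1.0, 1.0, 1.0, 1.0])
        b = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="constant"):
            median_bins(a, b)

    def test_independent_features_fill_quarters(self):
        for seed in range(1, 6):
            f1, f2, _ = additive_frame(m=4000, seed=seed)
            counts = median_bins(f1, f2).labels.value_counts(normalize=True)
            assert all(abs(counts[label] - 0.25) < 0.05 for label in combos.BIN_LABELS)

    def test_invariant_to_monotone_rescaling(self):
        f1, f2, _ = additive_frame(m=500, seed=3)
        base = median_bins(f1, f2).labels
        rescaled = median_bins(np.exp(f1 / 2), 5 * f2 - 7).labels
        assert (base == rescaled).all()


class TestBinSummary:
    def test_additive_ordering(self):
        for seed in range(1, 6):
            f1, f2, y = additive_frame(m=3000, seed=seed)
            summary, _ = bin_summary(median_bins(f1, f2), y)
            means = summary["mean"]
            assert means["HH"] > means["HL"] > means["LL"]
            assert means["HH"] > means["LH"] > means["LL"]
            assert abs(means["HL"] - means["LH"]) < 0.2

    def test_synergistic_pair_separates_only_hh(self):
        rng = np.random.default_rng(4)
        m = 3000
        f1 = pd.Series(rng.standard_normal(m), name="f1")
        f2 = pd.Series(rng.standard_normal(m), name="f2")
        y = pd.Series(np.maximum(f1, 0) * np.maximum(f2, 0) + 0.2 * rng.standard_normal(m))
        summary, _ = bin_summary(median_bins(f1, f2), y)
        means = summary["mean"]
        assert means["HH"] - means["LL"] > 5 * abs(means["HL"] - means["LL"])

    def test_constant_response_gives_identical_summaries(self):
        f1, f2, _ = additive_frame(m=1000, seed=5)
        flat = pd.Series(1.0, index=f1.index)
        summary, tests = bin_summary(median_bins(f1, f2), flat)
        assert summary["mean"].nunique() == 1
        assert np.allclose(tests["p"], 1.0)


class TestNetworkCombinationTests:
    @staticmethod
    def star_network(center, leaves, threshold=0.2):
        import networkx as nx

        g = nx.Graph()
        for leaf in leaves:
            g.add_edge(center, leaf, pcor=0.5, normalized_pcor=1.0)
        return pcnet.NetworkModel(graph=g, threshold=threshold)

    def test_three_neighbor_node_gets_six_regressors(self, small_scenario):
        data, _ = small_scenario
        net = self.star_network("exon_expr", ["H3K36me3", "H4K20me1", "gene_expr"])
        (comp,) = network_combination_tests(net, data, seed=1)
        assert len(comp.features) == 3
        from histonet.regress import fit_linear

        fit = fit_linear(data[comp.features], data["exon_expr"], interactions=True)
        assert fit.d == 1 + 3 + 3

    def test_additive_generator_yields_small_ratios(self):
        for seed in range(1, 6):
            data, _ = synth.scenario("small", m=3000, seed=seed)
            net = self.star_network("exon_expr", ["H3K36me3", "H4K20me1", "gene_expr"])
            (comp,) = network_combination_tests(net, data, seed=seed)
            assert abs(comp.improvement_ratio) <= 0.03

    def test_isolated_and_degree_one_nodes_skipped(self, small_scenario):
        data, _ = small_scenario
        net = self.star_network("exon_expr", ["H3K36me3"])
        assert network_combination_tests(net, data, seed=1) == []


class TestStepwiseBIC:
    def test_true_drivers_then_plateau(self):
        for seed in range(1, 6):
            data, truth = synth.scenario("small", m=3000, seed=seed)
            pc = pcnet.pairwise_partial_correlations(data)
            order = list(
                pc["exon_expr"].drop("exon_expr").abs()
                .sort_values(ascending=False).index
            )
            assert set(order[:3]) == {"H3K36me3", "H4K20me1", "gene_expr"}
            steps = stepwise_bic_by_pcor(data, "exon_expr", order)
            bic = steps["bic"].to_numpy()
            assert bic[1] - bic[2] > 100  # third driver still informative
            assert np.all(np.abs(np.diff(bic[2:])) < 30)  # then ~ ln(m)-scale noise

    def test_pure_noise_feature_costs_about_log_m(self):
        rng = np.random.default_rng(6)
        m = 3000
        data = pd.DataFrame(
            {
                "driver": rng.standard_normal(m),
                "noise": rng.standard_normal(m),
            }
        )
        data["y"] = data["driver"] + 0.5 * rng.standard_normal(m)
        steps = stepwise_bic_by_pcor(data, "y", ["driver", "noise"])
        assert steps["bic"].iloc[1] - steps["bic"].iloc[0] == pytest.approx(
            np.log(m), abs=6
        )

    def test_single_feature_sequence(self, small_scenario):
        data, _ = small_scenario
        steps = stepwise_bic_by_pcor(data, "exon_expr", ["H3K36me3"])
        assert len(steps) == 1

    def test_collinear_addition_dropped(self, small_scenario):
        data, _ = small_scenario
        data = data.copy()
        data["dup"] = data["H3K36me3"]
        steps = stepwise_bic_by_pcor(data, "exon_expr", ["H3K36me3", "dup", "H4K20me1"])
        assert list(steps["added"]) == ["H3K36me3", "H4K20me1"]


class TestClusterExport:
    def test_identical_features_adjacent_and_rows_ascending(self):
        rng = np.random.default_rng(7)
        m = 300
        base = rng.standard_normal(m)
        signals = pd.DataFrame(
            {
                "a": base,
                "b": rng.standard_normal(m),
                "a_copy": base,
                "c": rng.standard_normal(m),
            },
            index=[f"e{i}" for i in range(m)],
        )
        response = pd.Series(rng.standard_normal(m), index=signals.index)
        matrix, order = cluster_matrix_export(signals, response)
        assert abs(order.index("a") - order.index("a_copy")) == 1
        assert response.loc[matrix.index].is_monotonic_increasing

    def test_correlated_blocks_contiguous(self):
        rng = np.random.default_rng(8)
        m = 500
        block1 = rng.standard_normal(m)
        block2 = rng.standard_normal(m)
        signals = pd.DataFrame(
            {
                "p1": block1 + 0.2 * rng.standard_normal(m),
                "q1": block2 + 0.2 * rng.standard_normal(m),
                "p2": block1 + 0.2 * rng.standard_normal(m),
                "q2": block2 + 0.2 * rng.standard_normal(m),
            }
        )
        _, order = cluster_matrix_export(signals, pd.Series(rng.standard_normal(m)))
        p_pos = sorted(order.index(c) for c in ("p1", "p2"))
        assert p_pos[1] - p_pos[0] == 1
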