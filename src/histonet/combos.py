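"""Combinatorial-mode analyses of chromatin-feature pairs.

Addresses the accumulative-versus-synergistic question: if two marks act
additively, exon expression should step up whenever either mark is high
(LL < HL ~ LH < HH under median binning) and interaction regression terms
should buy essentially nothing; a synergistic pair would separate only the
HH bin and reward product terms.  Redundancy among marks is probed by
adding features to the regression in order of partial correlation and
watching the BIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .pcnet import NetworkModel
from .regress import ModelComparison, cross_validate, fit_linear, bic_of_fit

logger = logging.getLogger(__name__)

__all__ = [
    "BinAssignment",
    "median_bins",
    "bin_summary",
    "network_combination_tests",
    "stepwise_bic_by_pcor",
    "cluster_matrix_export",
]

BIN_LABELS = ["LL", "HL", "LH", "HH"]


@dataclass(slots=True)
class BinAssignment:
    """Median H/L binning of rows by two features.

    A row is High for a feature when its value strictly exceeds the
    feature's median (ties fall to Low); the first letter of the label is
    the first feature's state.
    """

    labels: pd.Series
    feature_a: str
    feature_b: str
    median_a: float
    median_b: float

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def median_bins(values_a: pd.Series, values_b: pd.Series) -> BinAssignment:
    """Partition rows into LL/HL/LH/HH by each feature's empirical median."""
    if len(values_a) != len(values_b):
        raise ValueError("feature vectors differ in length")
    if len(values_a) < 4:
        raise ValueError("need at least 4 rows to form four bins")
    med_a, med_b = float(values_a.median()), float(values_b.median())
    if values_a.nunique() == 1 or values_b.nunique() == 1:
        raise ValueError("constant feature vector; median binning degenerate")
    state_a = np.where(values_a.to_numpy() > med_a, "H", "L")
    state_b = np.where(values_b.to_numpy() > med_b, "H", "L")
    labels = pd.Series(
        [a + b for a, b in zip(state_a, state_b)], index=values_a.index, name="bin"
    )
    return BinAssignment(
        labels=labels,
        feature_a=values_a.name or "feature_a",
        feature_b=values_b.name or "feature_b",
        median_a=med_a,
        median_b=med_b,
    )


def bin_summary(bins: BinAssignment, response: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin response summaries and pairwise two-sided rank-sum tests.

    Returns (summary table indexed by bin, long-format table of
    Mann-Whitney p-values for every bin pair).
    """
    groups = {}
    for label in BIN_LABELS:
        vals = response.loc[bins.members(label)].to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"bin {label} is empty")
        groups[label] = vals
    summary = pd.DataFrame(
        {
            label: {
                "n": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
            for label, v in groups.items()
        }
    ).T
    summary.index.name = "bin"
    rows = []
    for a, b in combinations(BIN_LABELS, 2):
        stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"bin_a": a, "bin_b": b, "statistic": float(stat), "p": float(p)})
    return summary, pd.DataFrame(rows)


def network_combination_tests(
    network: NetworkModel,
    data: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> list[ModelComparison]:
    """Singleton vs interaction regressions for every network neighborhood.

    Each node with at least two neighbors is regressed on its neighbors,
    once with main effects only and once with all pairwise products, and
    the two models are compared by cross-validated Pearson r.  Nodes with
    fewer than two neighbors are skipped.
    """
    comparisons = []
    for node in sorted(network.graph.nodes):
        neigh = network.neighbors(node)
        if len(neigh) < 2:
            if neigh:
                logger.info("node %s has < 2 neighbors; skipped", node)
            continue
        X = data[neigh]
        y = data[node]
        p_single = cross_validate(X, y, k=k, seed=seed).mean_r
        p_inter = cross_validate(X, y, k=k, seed=seed, interactions=True).mean_r
        comparisons.append(
            ModelComparison(
                response=node, features=list(neigh),
                p_singleton=p_single, p_interaction=p_inter,
            )
        )
    return comparisons


def stepwise_bic_by_pcor(
    data: pd.DataFrame,
    response: str,
    order: list[str],
) -> pd.DataFrame:
    """BIC of response-on-first-k-features regressions, k = 1..len(order).

    ``order`` is the feature list sorted by descending |partial correlation
    with the response|.  Features whose addition makes the design
    rank-deficient are dropped with a warning.
    """
    if not order:
        raise ValueError("empty feature order")
    kept: list[str] = []
    rows = []
    y = data[response]
    for feat in order:
        candidate = kept + [feat]
        X = data[candidate]
        if np.linalg.matrix_rank(X.to_numpy()) < len(candidate):
            logger.warning("feature %s collinear with current set; dropped", feat)
            continue
        fit = fit_linear(X, y)
        kept.append(feat)
        rows.append({"k": len(kept), "added": feat, "bic": bic_of_fit(fit)})
    return pd.DataFrame(rows)


def cluster_matrix_export(
    signals: pd.DataFrame,
    response: pd.Series,
) -> tuple[pd.DataFrame, list[str]]:
    """Matrix export behind the clustered-heatmap view of mark redundancy.

    Rows are sorted by ascending response; features are ordered by
    average-linkage hierarchical clustering on correlation distance
    (1 - Pearson).  Returns the reordered matrix and the feature order.
    """
    if signals.shape[1] < 2:
        raise ValueError("need at least two features to cluster")
    row_order = response.sort_values(kind="mergesort").index
    corr = np.corrcoef(signals.to_numpy(dtype=float), rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    linkage = average(squareform(dist, checks=False))
    feature_order = [signals.columns[i] for i in leaves_list(linkage)]
    return signals.loc[row_order, feature_order], feature_order
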