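"""Full-conditional partial-correlation network with BIC threshold selection.

For V jointly observed variables (chromatin features, gene expression, exon
expression) the partial correlation of A and B given all remaining
variables is computed from the inverse correlation matrix Omega::

    pcor(A, B | rest) = -Omega_AB / sqrt(Omega_AA * Omega_BB)

which equals the correlation between the residuals of A and B after each is
regressed (with intercept) on the conditioning set; the residual route is
kept alongside as an independent cross-check.

Edges are selected by a BIC trace: pairs sorted by descending |pcor| are
added one at a time to a growing network whose score is the sum over nodes
of the OLS BIC of each node regressed on its current neighbors.  The
threshold is the |pcor| of the last pair whose BIC drop is at least a set
fraction (default 20%) of the maximum drop.  Significance of the threshold
is assessed against a permutation null in which every column is deranged
independently, so no value stays with its own row.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "partial_correlation_triple",
    "partial_correlation_residual",
    "pairwise_partial_correlations",
    "network_bic",
    "BICTrace",
    "bic_trace",
    "select_threshold",
    "PermutationResult",
    "permutation_null",
    "NetworkModel",
    "build_network",
]

logger = logging.getLogger(__name__)

COND_LIMIT = 1e10


def partial_correlation_triple(p_ab: float, p_ac: float, p_bc: float) -> float:
    """Partial correlation of A and B given a single variable C, closed form.

    (P_AB - P_AC*P_BC) / sqrt((1 - P_AC^2)(1 - P_BC^2)).
    """
    for name, v in (("P_AB", p_ab), ("P_AC", p_ac), ("P_BC", p_bc)):
        if abs(v) > 1:
            raise ValueError(f"{name} = {v} outside [-1, 1]")
    if abs(p_ac) == 1 or abs(p_bc) == 1:
        raise ValueError("conditioning variable perfectly correlated with A or B")
    return (p_ab - p_ac * p_bc) / math.sqrt((1 - p_ac**2) * (1 - p_bc**2))


def partial_correlation_residual(data: pd.DataFrame, a: str, b: str) -> float:
    """Residual-route partial correlation of columns ``a`` and ``b``.

    Both columns are OLS-regressed (with intercept) on every other column;
    the partial correlation is the Pearson correlation of the residuals.
    Serves as the definitional cross-check for the precision-matrix route.
    """
    others = [c for c in data.columns if c not in (a, b)]
    Z = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in others])
    resid = {}
    for col in (a, b):
        y = data[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid[col] = y - Z @ beta
    ra, rb = resid[a], resid[b]
    return float(np.dot(ra, rb) / math.sqrt(np.dot(ra, ra) * np.dot(rb, rb)))


def pairwise_partial_correlations(data: pd.DataFrame) -> pd.DataFrame:
    """Full-conditional partial correlations for every pair of columns.

    Computed from the inverse of the correlation matrix; requires more rows
    than columns and non-constant, non-collinear columns.
    """
    m, v = data.shape
    if m <= v:
        raise ValueError(f"need more rows than variables: m={m}, V={v}")
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    constant = [c for c, s in zip(data.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant columns: {constant}")
    corr = np.corrcoef(arr, rowvar=False)
    cond = np.linalg.cond(corr)
    if cond > COND_LIMIT:
        # point at the most nearly collinear columns via the smallest eigenvector
        w, vec = np.linalg.eigh(corr)
        worst = np.argsort(-np.abs(vec[:, 0]))[:3]
        names = [data.columns[i] for i in worst]
        raise ValueError(
            f"correlation matrix near-singular (cond={cond:.3g}); "
            f"near-collinear columns likely among {names}"
        )
    omega = np.linalg.inv(corr)
    dd = np.sqrt(np.outer(np.diag(omega), np.diag(omega)))
    pcor = -omega / dd
    np.fill_diagonal(pcor, 1.0)
    return pd.DataFrame(pcor, index=data.columns, columns=data.columns)


def _node_bic(arr: np.ndarray, node: int, neighbors: tuple[int, ...]) -> float:
    """BIC of OLS of column ``node`` on ``neighbors`` (intercept-only if none)."""
    m = arr.shape[0]
    y = arr[:, node]
    if neighbors:
        X = np.column_stack([np.ones(m), arr[:, list(neighbors)]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        d = len(neighbors) + 1
    else:
        rss = float(np.sum((y - y.mean()) ** 2))
        d = 1
    if rss <= 0:
        raise ValueError(f"degenerate regression for node {node}: RSS = 0")
    return m * (math.log(2 * math.pi * rss / m) + 1) + d * math.log(m)


def network_bic(data: pd.DataFrame, edges) -> float:
    """Score an undirected edge set: sum over nodes of node-on-neighbors BIC.

    Each node (column) is regressed with intercept on its current neighbors;
    isolated nodes contribute their intercept-only BIC.  This degenerates to
    the single-model BIC when only one response node has neighbors.
    """
    cols = list(data.columns)
    pos = {c: i for i, c in enumerate(cols)}
    neighbors: dict[int, set[int]] = {i: set() for i in range(len(cols))}
    for a, b in edges:
        ia, ib = pos[a], pos[b]
        neighbors[ia].add(ib)
        neighbors[ib].add(ia)
    arr = data.to_numpy(dtype=float)
    return sum(_node_bic(arr, i, tuple(sorted(nb))) for i, nb in neighbors.items())


@dataclass(slots=True)
class BICTrace:
    """BIC scores of the nested networks grown by adding sorted pairs.

    ``pairs`` are sorted by descending |pcor| (ties broken by pair name);
    ``bics[i]`` is the score of the network containing the first i pairs
    (``bics[0]`` is the empty network), so ``diffs[i] = bics[i] - bics[i+1]``
    is the drop achieved by pair i.  ``selected_index`` is the number of
    pairs kept; ``threshold`` is the |pcor| of the last kept pair.
    """

    pairs: list[tuple[str, str]]
    pcors: np.ndarray
    bics: np.ndarray
    diffs: np.ndarray
    selected_index: int | None = None
    threshold: float | None = None

    @property
    def max_diff(self) -> float:
        return float(self.diffs.max())

    def selected_edges(self) -> list[tuple[str, str]]:
        if self.selected_index is None:
            raise ValueError("run select_threshold first")
        return self.pairs[: self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": [a for a, _ in self.pairs],
                "node_b": [b for _, b in self.pairs],
                "pcor": self.pcors,
                "bic": self.bics[1:],
                "bic_diff": self.diffs,
            }
        )


def bic_trace(data: pd.DataFrame, pcors: pd.DataFrame | None = None) -> BICTrace:
    """Grow nested networks over all pairs sorted by descending |pcor|.

    Adding one pair only changes the neighborhoods of its two endpoints, so
    each step re-scores just those two node regressions.
    """
    if pcors is None:
        pcors = pairwise_partial_correlations(data)
    cols = list(data.columns)
    pos = {c: i for i, c in enumerate(cols)}
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    pairs.sort(key=lambda p: (-abs(pcors.loc[p[0], p[1]]), p))
    if len(pairs) < 1:
        raise ValueError("need at least one pair")

    arr = data.to_numpy(dtype=float)
    neighbors: dict[int, set[int]] = {i: set() for i in range(len(cols))}
    node_bics = np.array([_node_bic(arr, i, ()) for i in range(len(cols))])
    bics = [float(node_bics.sum())]
    for a, b in pairs:
        ia, ib = pos[a], pos[b]
        neighbors[ia].add(ib)
        neighbors[ib].add(ia)
        for i in (ia, ib):
            node_bics[i] = _node_bic(arr, i, tuple(sorted(neighbors[i])))
        bics.append(float(node_bics.sum()))
    bics_arr = np.array(bics)
    return BICTrace(
        pairs=pairs,
        pcors=np.array([pcors.loc[a, b] for a, b in pairs]),
        bics=bics_arr,
        diffs=bics_arr[:-1] - bics_arr[1:],
    )


def select_threshold(trace: BICTrace, fraction: float = 0.2) -> float:
    """Pick the partial-correlation threshold from the BIC trace.

    A pair is a "large" step when its BIC drop is at least ``fraction`` of
    the maximum drop.  All pairs up to and including the *last* large step
    become edges; the threshold is that pair's |pcor|.  Earlier small dips
    do not truncate the network.
    """
    if len(trace.pairs) == 1:
        warnings.warn("single pair in trace; kept by default", stacklevel=2)
        trace.selected_index = 1
        trace.threshold = float(abs(trace.pcors[0]))
        return trace.threshold
    cutoff = fraction * trace.max_diff
    qualifying = np.nonzero(trace.diffs >= cutoff)[0]
    last = int(qualifying[-1])
    trace.selected_index = last + 1
    trace.threshold = float(abs(trace.pcors[last]))
    return trace.threshold


def _derangement_rows(m: int, rng: np.random.Generator) -> np.ndarray:
    if m < 2:
        raise ValueError("cannot permute fewer than 2 rows")
    if m == 2:
        return np.array([1, 0])
    while True:
        perm = rng.permutation(m)
        if not np.any(perm == np.arange(m)):
            return perm


@dataclass(slots=True)
class PermutationResult:
    """Pooled permutation null for pairwise partial correlations."""

    null_pcors: np.ndarray       # all off-diagonal pcors, all permutations
    null_mean: float
    null_sd: float
    max_abs_null: float
    threshold: float | None
    z: float | None
    n_perm: int


def permutation_null(
    data: pd.DataFrame,
    threshold: float | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Recompute all pairwise partial correlations under column derangements.

    Each permutation deranges every column independently (no value keeps its
    row), destroying all cross-column association while preserving each
    column's marginal distribution exactly.  Off-diagonal pcors are pooled
    across permutations; the z-score locates ``threshold`` in that null.
    """
    m, v = data.shape
    if m < 2:
        raise ValueError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    arr = data.to_numpy(dtype=float)
    iu = np.triu_indices(v, k=1)
    pooled = []
    for _ in range(n_perm):
        permuted = np.column_stack(
            [arr[_derangement_rows(m, rng), j] for j in range(v)]
        )
        corr = np.corrcoef(permuted, rowvar=False)
        omega = np.linalg.inv(corr)
        dd = np.sqrt(np.outer(np.diag(omega), np.diag(omega)))
        pcor = -omega / dd
        pooled.append(pcor[iu])
    null = np.concatenate(pooled)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    z = None if threshold is None else float((threshold - mean) / sd)
    return PermutationResult(
        null_pcors=null,
        null_mean=mean,
        null_sd=sd,
        max_abs_null=float(np.abs(null).max()),
        threshold=threshold,
        z=z,
        n_perm=n_perm,
    )


@dataclass(slots=True)
class NetworkModel:
    """The undirected partial-correlation network.

    Edge weights are raw signed pcors; ``normalized`` weights divide by the
    maximum absolute edge weight so the strongest edge has weight +/-1.
    When a response column is named, each node also carries its (normalized)
    partial correlation with the response.
    """

    graph: nx.Graph
    threshold: float

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "pcor": d["pcor"],
                "normalized_pcor": d["normalized_pcor"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "pcor", "normalized_pcor"])

    def neighbors(self, node: str) -> list[str]:
        return sorted(self.graph.neighbors(node))


def build_network(
    pcors: pd.DataFrame,
    threshold: float,
    response: str | None = None,
) -> NetworkModel:
    """Assemble the undirected network of pairs with |pcor| >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    cols = list(pcors.columns)
    g.add_nodes_from(cols)
    kept = [
        (a, b, float(pcors.loc[a, b]))
        for i, a in enumerate(cols)
        for b in cols[i + 1 :]
        if abs(pcors.loc[a, b]) >= threshold
    ]
    max_abs = max((abs(w) for _, _, w in kept), default=1.0)
    for a, b, w in kept:
        g.add_edge(a, b, pcor=w, normalized_pcor=w / max_abs)
    if response is not None and response in cols:
        col = pcors[response].drop(response)
        denom = float(col.abs().max()) or 1.0
        for node in g.nodes:
            if node == response:
                continue
            g.nodes[node]["pcor_with_response"] = float(pcors.loc[node, response])
            g.nodes[node]["normalized_pcor_with_response"] = float(pcors.loc[node, response]) / denom
    return NetworkModel(graph=g, threshold=threshold)
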