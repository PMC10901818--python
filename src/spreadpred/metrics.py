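"""Iterative topological metrics and the classic-centrality benchmark set.

Three iterative metric families are computed, each encoding one hop more
of a node's neighbourhood per iteration and converging to a global
centrality:

* NWC (normalized walk count): power iteration ``w(k) = A w(k-1) / ||.||``
  from the L2-normalized all-one vector; order k is the L2-normalized
  number of distinct k-hop walks from each node; converges to eigenvector
  centrality.
* VP (visiting probability): the PageRank iteration
  ``p_i(k) = alpha * sum_j A_ji p_j(k-1)/d_j + (1-alpha)/N`` from the
  uniform distribution; order k is the occupation probability of a
  teleporting random walker after k steps; converges to PageRank.
  Note order k uses (k+1)-hop information, since neighbour degrees enter
  the update.
* HI (iterative H-index): start from degree and repeatedly apply the
  Hirsch operator to neighbour values; monotone non-increasing per node
  and reaches the coreness in finitely many steps.

``benchmark_centralities`` assembles the 7-metric comparison feature set:
degree, neighbourhood (sum of neighbour degrees), two-hop neighbourhood
(sum of degrees of nodes exactly two hops away), coreness, eigenvector
centrality, PageRank and closeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from .graph import UndirectedGraph, distance_matrix, is_connected

#: convergence tolerance (L1 on successive iterates) for the "converged"
#: eigenvector / PageRank benchmarks, and the iteration cap
CONVERGENCE_TOL = 1e-10
MAX_ITER = 1000

DEFAULT_ALPHA = 0.85  # PageRank teleportation parameter


@dataclass
class IterativeMetricSet:
    """Per-node values of one iterative metric for orders 1..K.

    ``values[:, k-1]`` holds order k for all nodes.
    """

    metric_name: str  # {"NWC", "VP", "HI"}
    values: np.ndarray  # shape (N, K)
    alpha: float | None = None  # VP only

    @property
    def K(self) -> int:
        return self.values.shape[1]

    def order(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.K:
            raise ValueError(f"order {k} outside 1..{self.K}")
        return self.values[:, k - 1]


@dataclass
class CentralityVector:
    """One converged global centrality, one value per node."""

    metric_name: str
    values: np.ndarray


def _require_edges(g: UndirectedGraph) -> None:
    if g.edge_count == 0:
        raise ValueError("graph has no edges")


def nwc_iterate(g: UndirectedGraph, K: int) -> IterativeMetricSet:
    """Normalized walk counts of orders 1..K (power-iteration truncation).

    Column k equals ``A^k u / ||A^k u||_2``; entries are non-negative and
    each column has unit Euclidean norm.
    """
    _require_edges(g)
    if K < 1:
        raise ValueError("K must be >= 1")
    a = g.to_sparse()
    n = g.node_count
    w = np.ones(n) / np.sqrt(n)
    cols = np.empty((n, K))
    for k in range(K):
        w = a @ w
        norm = np.linalg.norm(w)
        if norm == 0.0:  # only possible without edges; guarded above
            raise ValueError("walk-count vector vanished")
        w /= norm
        cols[:, k] = w
    return IterativeMetricSet("NWC", cols)


def vp_iterate(g: UndirectedGraph, K: int,
               alpha: float = DEFAULT_ALPHA) -> IterativeMetricSet:
    """Visiting probabilities of orders 1..K (PageRank iteration).

    Every column is a probability distribution over nodes.  Requires no
    isolated nodes (restrict to the largest connected component first).
    """
    _require_edges(g)
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    deg = g.degrees.astype(float)
    if (deg == 0).any():
        raise ValueError("isolated node: VP update divides by degree")
    a = g.to_sparse()
    n = g.node_count
    p = np.full(n, 1.0 / n)
    cols = np.empty((n, K))
    for k in range(K):
        p = alpha * (a @ (p / deg)) + (1.0 - alpha) / n
        cols[:, k] = p
    return IterativeMetricSet("VP", cols, alpha=alpha)


def hirsch_operator(values: np.ndarray) -> int:
    """Largest integer x such that at least x of ``values`` are >= x (0 if empty)."""
    if len(values) == 0:
        return 0
    desc = np.sort(values)[::-1]
    return int(np.sum(desc >= np.arange(1, len(desc) + 1)))


def hi_iterate(g: UndirectedGraph, K: int) -> IterativeMetricSet:
    """Iterative H-indices of orders 1..K; order 1 is the degree.

    Per node the sequence is non-increasing in k and stabilizes at the
    node's coreness.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = g.node_count
    h = g.degrees.astype(np.int64)
    cols = np.empty((n, K), dtype=np.int64)
    cols[:, 0] = h
    for k in range(1, K):
        h = np.array([hirsch_operator(h[g.neighbors(i)]) for i in range(n)])
        cols[:, k] = h
    return IterativeMetricSet("HI", cols)


def hi_fixed_point(g: UndirectedGraph, max_iter: int = MAX_ITER) -> np.ndarray:
    """Iterate the H-operator to its fixed point (the coreness vector)."""
    h = g.degrees.astype(np.int64)
    for _ in range(max_iter):
        nxt = np.array([hirsch_operator(h[g.neighbors(i)])
                        for i in range(g.node_count)])
        if (nxt == h).all():
            return h
        h = nxt
    raise RuntimeError("H-index iteration did not reach a fixed point")


# -- converged global centralities ------------------------------------


def eigenvector_centrality(g: UndirectedGraph, tol: float = CONVERGENCE_TOL,
                           max_iter: int = MAX_ITER) -> CentralityVector:
    """Principal eigenvector of A by power iteration, L2-normalized."""
    _require_edges(g)
    a = g.to_sparse()
    w = np.ones(g.node_count) / np.sqrt(g.node_count)
    for _ in range(max_iter):
        nxt = a @ w
        nxt /= np.linalg.norm(nxt)
        if np.abs(nxt - w).sum() < tol:
            return CentralityVector("eigenvector", nxt)
        w = nxt
    return CentralityVector("eigenvector", w)


def pagerank(g: UndirectedGraph, alpha: float = DEFAULT_ALPHA,
             tol: float = CONVERGENCE_TOL,
             max_iter: int = MAX_ITER) -> CentralityVector:
    """PageRank fixed point of the VP iteration."""
    deg = g.degrees.astype(float)
    if (deg == 0).any():
        raise ValueError("isolated node: PageRank undefined here")
    a = g.to_sparse()
    n = g.node_count
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = alpha * (a @ (p / deg)) + (1.0 - alpha) / n
        if np.abs(nxt - p).sum() < tol:
            return CentralityVector("pagerank", nxt)
        p = nxt
    return CentralityVector("pagerank", p)


def coreness(g: UndirectedGraph) -> CentralityVector:
    """k-core number per node (standard peeling decomposition)."""
    import networkx as nx

    core = nx.core_number(g.to_networkx())
    return CentralityVector(
        "coreness", np.array([core[i] for i in range(g.node_count)], dtype=float))


def benchmark_centralities(g: UndirectedGraph) -> list[CentralityVector]:
    """The 7 classic centralities used by the comparison model.

    Order: degree, neighborhood, two-hop neighborhood, coreness,
    eigenvector, PageRank, closeness.  Requires a connected graph
    (closeness averages over all pairs).
    """
    if not is_connected(g):
        raise ValueError("benchmark centralities need a connected graph")
    deg = g.degrees.astype(float)
    a = g.to_sparse()
    neighborhood = a @ deg
    dist = distance_matrix(g)
    two_hop = np.array([deg[dist[i] == 2].sum() for i in range(g.node_count)])
    closeness = (g.node_count - 1) / dist.sum(axis=1)
    return [
        CentralityVector("degree", deg),
        CentralityVector("neighborhood", neighborhood),
        CentralityVector("two_hop_neighborhood", two_hop),
        coreness(g),
        eigenvector_centrality(g),
        pagerank(g),
        CentralityVector("closeness", closeness),
    ]


def benchmark_feature_matrix(g: UndirectedGraph) -> np.ndarray:
    """The 7 benchmark centralities as an N x 7 feature matrix."""
    return np.column_stack([c.values for c in benchmark_centralities(g)])


def convergence_profile(ms: IterativeMetricSet,
                        target: CentralityVector) -> np.ndarray:
    """Kendall tau-b between each order M(k) and the converged metric M*."""
    if len(target.values) != ms.values.shape[0]:
        raise ValueError("metric set and target are on different node sets")
    return np.array([
        kendalltau(ms.order(k), target.values).statistic
        for k in range(1, ms.K + 1)
    ])
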