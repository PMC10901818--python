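"""Undirected graph container, edge-list I/O and structural descriptors.

The package works on simple, undirected, unweighted graphs with dense
0-based node indices.  Adjacency is stored in CSR form (``indptr`` /
``indices``), which is what the SIR kernel and the iterative metric
updates consume directly.  Original node labels from an input file are
preserved so results can be written back in terms of the user's ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list input, with the offending line number."""


@dataclass
class UndirectedGraph:
    """Simple unweighted undirected graph in CSR adjacency form.

    Invariants: no self-loops, no parallel edges, symmetric adjacency,
    ``degrees.sum() == 2 * edge_count``.
    """

    indptr: np.ndarray
    indices: np.ndarray
    labels: list | None = None

    @property
    def node_count(self) -> int:
        return len(self.indptr) - 1

    @property
    def edge_count(self) -> int:
        return len(self.indices) // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.edge_count / self.node_count

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def label_of(self, i: int):
        return self.labels[i] if self.labels is not None else i

    def index_of(self, label) -> int:
        if self.labels is None:
            return int(label)
        return self.labels.index(label)

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], n: int | None = None,
                   labels: list | None = None) -> "UndirectedGraph":
        """Build from an iterable of (i, j) pairs; simplifies on the way in."""
        arr = np.asarray(list(edges), dtype=np.int64)
        if arr.size == 0:
            if n is None:
                raise ValueError("empty edge set and no node count given")
            arr = arr.reshape(0, 2)
        lo = np.minimum(arr[:, 0], arr[:, 1]) if len(arr) else np.empty(0, np.int64)
        hi = np.maximum(arr[:, 0], arr[:, 1]) if len(arr) else np.empty(0, np.int64)
        keep = lo != hi  # drop self-loops
        pairs = np.unique(np.column_stack([lo[keep], hi[keep]]), axis=0)
        if n is None:
            n = int(pairs.max()) + 1 if len(pairs) else 0
        row = np.concatenate([pairs[:, 0], pairs[:, 1]])
        col = np.concatenate([pairs[:, 1], pairs[:, 0]])
        a = sparse.csr_array((np.ones(len(row), np.int8), (row, col)), shape=(n, n))
        a.sort_indices()
        return cls(indptr=a.indptr.astype(np.int64),
                   indices=a.indices.astype(np.int64), labels=labels)

    @classmethod
    def from_networkx(cls, g) -> "UndirectedGraph":
        nodes = sorted(g.nodes())
        idx = {v: i for i, v in enumerate(nodes)}
        edges = [(idx[u], idx[v]) for u, v in g.edges() if u != v]
        return cls.from_edges(edges, n=len(nodes), labels=nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        for i in range(self.node_count):
            for j in self.neighbors(i):
                if i < j:
                    g.add_edge(i, int(j))
        return g

    def to_sparse(self, dtype=float) -> sparse.csr_array:
        n = self.node_count
        return sparse.csr_array(
            (np.ones(len(self.indices), dtype=dtype), self.indices, self.indptr),
            shape=(n, n))

    def validate(self) -> None:
        """Check the simple-graph invariants; raises AssertionError on violation."""
        a = self.to_sparse(dtype=np.int8)
        assert (a != a.T).nnz == 0, "adjacency not symmetric"
        assert a.diagonal().sum() == 0, "self-loops present"
        assert int(self.degrees.sum()) == 2 * self.edge_count


@dataclass
class Partition:
    """Community assignment: one integer community id per node."""

    community: np.ndarray

    def __post_init__(self):
        self.community = np.asarray(self.community, dtype=np.int64)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.community))

    def groups(self) -> list[np.ndarray]:
        order = np.argsort(self.community, kind="stable")
        ids = self.community[order]
        cuts = np.flatnonzero(np.diff(ids)) + 1
        return np.split(order, cuts)


# -- I/O ---------------------------------------------------------------


def read_edge_list(path, dialect: str = "plain") -> UndirectedGraph:
    """Read a whitespace-separated edge list into a simplified graph.

    Both dialects skip ``%``-prefixed comment lines (the KONECT ``out.*``
    header convention).  Directions, self-loops and duplicate edges are
    discarded; labels are mapped to dense 0-based indices in order of
    first appearance (retrievable through ``labels``).
    """
    if dialect not in ("plain", "konect"):
        raise ValueError(f"unknown dialect {dialect!r}")
    labels: dict = {}
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("%") or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if dialect == "konect" and len(tokens) in (3, 4):
                tokens = tokens[:2]  # optional weight / timestamp columns
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}")
            ij = []
            for t in tokens:
                if t not in labels:
                    labels[t] = len(labels)
                ij.append(labels[t])
            edges.append((ij[0], ij[1]))
    if not edges:
        raise EdgeListParseError(f"{path}: empty edge set")
    g = UndirectedGraph.from_edges(edges, n=len(labels), labels=list(labels))
    if g.edge_count == 0:
        raise EdgeListParseError(f"{path}: no edges left after simplification")
    return g


def write_edge_list(g: UndirectedGraph, path) -> None:
    with open(path, "w") as fh:
        for i in range(g.node_count):
            for j in g.neighbors(i):
                if i < j:
                    fh.write(f"{g.label_of(i)} {g.label_of(int(j))}\n")


def graph_summary(g: UndirectedGraph) -> dict:
    """Summary dict ``{n, m, mean_degree, diameter}`` (diameter needs connectivity)."""
    return {
        "n": g.node_count,
        "m": g.edge_count,
        "mean_degree": g.mean_degree,
        "diameter": diameter(g),
    }


def write_summary(g: UndirectedGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph_summary(g), fh, indent=1)


# -- structure ---------------------------------------------------------


def is_connected(g: UndirectedGraph) -> bool:
    ncomp, _ = csgraph.connected_components(g.to_sparse(), directed=False)
    return ncomp == 1


def largest_connected_component(
        g: UndirectedGraph, partition: Partition | None = None,
        return_index: bool = False):
    """Induced subgraph on the largest component, reindexed.

    Diameter and closeness are only defined on connected graphs, so every
    analysis in this package runs on the LCC of its input.  If a
    ``partition`` is given it is restricted alongside; with
    ``return_index`` the kept original indices are returned too.
    """
    ncomp, comp = csgraph.connected_components(g.to_sparse(), directed=False)
    if ncomp == 1:
        out = (g, partition, np.arange(g.node_count))
    else:
        largest = np.argmax(np.bincount(comp))
        keep = np.flatnonzero(comp == largest)
        remap = -np.ones(g.node_count, dtype=np.int64)
        remap[keep] = np.arange(len(keep))
        edges = []
        for i in keep:
            for j in g.neighbors(i):
                if i < j:
                    edges.append((remap[i], remap[j]))
        labels = [g.label_of(int(i)) for i in keep]
        sub = UndirectedGraph.from_edges(edges, n=len(keep), labels=labels)
        part = Partition(partition.community[keep]) if partition is not None else None
        out = (sub, part, keep)
    results = [out[0]]
    if partition is not None:
        results.append(out[1])
    if return_index:
        results.append(out[2])
    return results[0] if len(results) == 1 else tuple(results)


def distance_matrix(g: UndirectedGraph) -> np.ndarray:
    """All-pairs hop distances (BFS); ``inf`` marks unreachable pairs."""
    return csgraph.shortest_path(g.to_sparse(), method="D", unweighted=True)


def diameter(g: UndirectedGraph, dist: np.ndarray | None = None) -> int:
    """Largest shortest-path length between any node pair."""
    if dist is None:
        dist = distance_matrix(g)
    dmax = dist.max()
    if np.isinf(dmax):
        raise ValueError(
            "graph is disconnected; extract the largest connected component first")
    return int(dmax)


def modularity(g: UndirectedGraph, part: Partition) -> float:
    """Newman modularity Q = sum_c [ l_c/m - (d_c / 2m)^2 ] of a partition."""
    m = g.edge_count
    if m == 0:
        raise ValueError("modularity undefined for an empty edge set")
    if len(part.community) != g.node_count:
        raise ValueError("partition does not cover all nodes")
    deg = g.degrees
    q = 0.0
    comm = part.community
    for group in part.groups():
        mask = np.zeros(g.node_count, dtype=bool)
        mask[group] = True
        intra = sum(int(mask[g.neighbors(i)].sum()) for i in group) // 2
        dc = int(deg[group].sum())
        q += intra / m - (dc / (2.0 * m)) ** 2
    return q


def mixing_fraction(g: UndirectedGraph, part: Partition) -> float:
    """Mean over nodes of the fraction of a node's links leaving its community."""
    comm = part.community
    fr = np.empty(g.node_count)
    for i in range(g.node_count):
        nbrs = g.neighbors(i)
        fr[i] = np.mean(comm[nbrs] != comm[i]) if len(nbrs) else 0.0
    return float(fr.mean())


def khop_coverage(g: UndirectedGraph, k: int,
                  dist: np.ndarray | None = None) -> float:
    """Average fraction of nodes within k hops of a node (source included).

    Non-decreasing in k; equals 1 once k reaches the diameter.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if dist is None:
        dist = distance_matrix(g)
    if np.isinf(dist.max()):
        raise ValueError(
            "graph is disconnected; extract the largest connected component first")
    return float((dist <= k).mean())


def coverage_curve(g: UndirectedGraph, k_max: int | None = None) -> np.ndarray:
    """Coverage for k = 1..k_max (default: up to the diameter)."""
    dist = distance_matrix(g)
    if k_max is None:
        k_max = diameter(g, dist)
    return np.array([khop_coverage(g, k, dist) for k in range(1, k_max + 1)])


def node_property_table(g: UndirectedGraph, columns: dict[str, Sequence]
                        ) -> "pandas.DataFrame":  # noqa: F821
    """Node-property table with original labels, ``node,degree,...``."""
    import pandas as pd

    data = {"node": [g.label_of(i) for i in range(g.node_count)],
            "degree": g.degrees}
    data.update(columns)
    return pd.DataFrame(data)
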