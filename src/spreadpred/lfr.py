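"""LFR benchmark networks and deterministic toy fixtures.

The Lancichinetti–Fortunato–Radicchi (LFR) benchmark generates networks
with a power-law degree distribution (exponent tau1), power-law
community sizes (exponent tau2) and a tunable mixing parameter mu — the
fraction of each node's links that leave its community.  The defaults
reproduce the study conditions used throughout this package: N = 1000
(N = 10000 available), tau1 = 2, tau2 = 3, mean degree 10, maximum
degree sqrt(10 N)/2, community sizes in [50, sqrt(10 N)].

The construction is implemented here directly rather than delegated:
degrees are drawn from a truncated power law whose lower cut-off is
calibrated so the realized mean degree matches the target; each node's
external degree is mu * degree with stochastic rounding (so the
realized per-node mixing averages mu even when mu * degree < 1);
intra-community and inter-community edges are wired by configuration
models made simple by rewiring fix-ups.  Generated graphs are validated
(simple-graph invariants, realized mean degree within 15% of target,
realized mixing close to mu) and returned as their largest connected
component with the planted partition.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .graph import (Partition, UndirectedGraph, largest_connected_component,
                    mixing_fraction)


class LFRGenerationError(RuntimeError):
    pass


@dataclass
class LFRConfig:
    """Parameters of the LFR benchmark (defaults: the N=1000 study suite)."""

    n: int = 1000
    mu: float = 0.1
    tau1: float = 2.0            # degree exponent
    tau2: float = 3.0            # community-size exponent
    mean_degree: float = 10.0
    max_degree: int | None = None            # default sqrt(10 N)/2
    community_size_range: tuple[int, int] | None = None  # default [50, sqrt(10 N)]
    rng_seed: int = 0
    max_attempts: int = 10

    def __post_init__(self):
        if self.tau1 < 2:
            raise ValueError("tau1 must be >= 2")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.max_degree is None:
            self.max_degree = int(round(math.sqrt(10 * self.n) / 2))
        if self.community_size_range is None:
            self.community_size_range = (
                min(50, self.n), int(round(math.sqrt(10 * self.n))))
        lo, hi = self.community_size_range
        if not lo <= hi <= self.n:
            raise ValueError("community sizes must satisfy min <= max <= N")


def _discrete_powerlaw(rng, tau, lo, hi, size):
    """Samples from p(k) proportional to k^-tau on the integers [lo, hi]."""
    k = np.arange(lo, hi + 1)
    p = k ** (-float(tau))
    return rng.choice(k, size=size, p=p / p.sum())


def _powerlaw_mean(tau, lo, hi) -> float:
    k = np.arange(lo, hi + 1, dtype=float)
    p = k ** (-float(tau))
    return float((k * p).sum() / p.sum())


def _solve_min_degree(tau, mean_target, dmax) -> int:
    """Integer lower cut-off whose discrete power-law mean is closest to target."""
    candidates = np.arange(1, dmax)
    means = np.array([_powerlaw_mean(tau, c, dmax) for c in candidates])
    return int(candidates[np.argmin(np.abs(means - mean_target))])


def _community_sizes(rng, tau2, cmin, cmax, n, max_tries=1000):
    for _ in range(max_tries):
        sizes: list[int] = []
        while sum(sizes) < n:
            sizes.append(int(_discrete_powerlaw(rng, tau2, cmin, cmax, 1)[0]))
        excess = sum(sizes) - n
        sizes.sort(reverse=True)
        for i in range(len(sizes)):
            take = min(excess, sizes[i] - cmin)
            sizes[i] -= take
            excess -= take
        if excess == 0:
            return sizes
    raise LFRGenerationError("no feasible community size sequence")


def _pair_stubs_simple(rng, stubs, adj, comm=None, max_sweeps=60):
    """Configuration-model pairing made simple by rewiring against good edges.

    ``adj`` (set of sorted edge tuples) is shared across calls so intra-
    and inter-community wiring cannot duplicate each other.  When ``comm``
    is given, edges inside one community are forbidden (inter wiring).
    A handful of unresolvable stubs may be dropped, costing a tiny degree
    deficiency.
    """
    edges: list[tuple[int, int]] = []
    stubs = np.array(stubs, dtype=np.int64)
    rng.shuffle(stubs)
    pending = list(zip(stubs[0::2], stubs[1::2]))
    for _ in range(max_sweeps):
        bad = []
        for u, v in pending:
            u, v = int(u), int(v)
            key = (u, v) if u < v else (v, u)
            if u == v or key in adj or (comm is not None and comm[u] == comm[v]):
                bad.append((u, v))
            else:
                adj.add(key)
                edges.append(key)
        if not bad:
            return edges
        pending = []
        if not edges:
            flat = np.array(bad, dtype=np.int64).ravel()
            rng.shuffle(flat)
            pending = list(zip(flat[0::2], flat[1::2]))
            continue
        for u, v in bad:
            j = int(rng.integers(len(edges)))
            x, y = edges[j]
            done = False
            for a, b in (((u, x), (v, y)), ((u, y), (v, x))):
                e1 = tuple(sorted(a))
                e2 = tuple(sorted(b))
                ok = (e1[0] != e1[1] and e2[0] != e2[1] and e1 != e2
                      and e1 not in adj and e2 not in adj)
                if ok and comm is not None:
                    ok = comm[e1[0]] != comm[e1[1]] and comm[e2[0]] != comm[e2[1]]
                if ok:
                    adj.discard((x, y) if x < y else (y, x))
                    edges[j] = e1
                    adj.add(e1)
                    adj.add(e2)
                    edges.append(e2)
                    done = True
                    break
            if not done:
                pending.append((u, v))
        if not pending:
            return edges
    return edges


def _generate_once(cfg: LFRConfig, seed: int):
    rng = np.random.default_rng(seed)
    n, mu = cfg.n, cfg.mu
    dmax = cfg.max_degree
    cmin, cmax = cfg.community_size_range
    dmin = _solve_min_degree(cfg.tau1, cfg.mean_degree, dmax)
    deg = _discrete_powerlaw(rng, cfg.tau1, dmin, dmax, n)
    # external degree: stochastic rounding keeps E[ext_i] = mu * d_i
    ext = np.floor(mu * deg).astype(np.int64)
    ext += (rng.random(n) < (mu * deg - np.floor(mu * deg))).astype(np.int64)
    intra = deg - ext
    sizes = _community_sizes(rng, cfg.tau2, cmin, cmax, n)
    # nodes with the largest intra degree get placed first
    order = np.argsort(-intra)
    cap = list(sizes)
    comm = np.full(n, -1, dtype=np.int64)
    members: list[list[int]] = [[] for _ in sizes]
    for node in order:
        feasible = [c for c in range(len(sizes))
                    if cap[c] > 0 and intra[node] <= sizes[c] - 1]
        if not feasible:
            c = int(np.argmax(sizes))
            intra[node] = sizes[c] - 1     # hub: clamp to fit the largest community
            ext[node] = deg[node] - intra[node]
            feasible = ([c] if cap[c] > 0
                        else [i for i in range(len(sizes)) if cap[i] > 0])
        c = int(rng.choice(feasible))
        comm[node] = c
        cap[c] -= 1
        members[c].append(int(node))
    adj: set = set()
    edges: list[tuple[int, int]] = []
    for mem in members:
        mem_arr = np.array(mem, dtype=np.int64)
        if len(mem_arr) and intra[mem_arr].sum() % 2:
            i = mem_arr[int(np.argmax(intra[mem_arr]))]
            intra[i] -= 1
            ext[i] += 1
        edges += _pair_stubs_simple(rng, np.repeat(mem_arr, intra[mem_arr]), adj)
    if ext.sum() % 2:
        ext[int(np.argmax(ext))] -= 1
    edges += _pair_stubs_simple(rng, np.repeat(np.arange(n), ext), adj, comm=comm)
    g = UndirectedGraph.from_edges(edges, n=n)
    return largest_connected_component(g, Partition(comm))


def generate_lfr(cfg: LFRConfig) -> tuple[UndirectedGraph, Partition]:
    """Generate one LFR network; retries with derived seeds on failure.

    Returns the largest connected component and the planted partition
    restricted to it.  Raises :class:`LFRGenerationError` with
    diagnostics if no attempt satisfies the validity checks (simple
    graph, mean degree within 15% of target, most nodes retained,
    realized mixing close to mu).
    """
    seeds = np.random.SeedSequence(cfg.rng_seed).generate_state(
        cfg.max_attempts, np.uint32) >> 1
    failures = []
    for attempt, seed in enumerate(seeds):
        g, part = _generate_once(cfg, int(seed))
        g.validate()
        problems = []
        if abs(g.mean_degree - cfg.mean_degree) > 0.15 * cfg.mean_degree:
            problems.append(f"mean degree {g.mean_degree:.2f} "
                            f"vs target {cfg.mean_degree}")
        if g.node_count < 0.9 * cfg.n:
            problems.append(f"LCC kept only {g.node_count}/{cfg.n} nodes")
        mix = mixing_fraction(g, part)
        if abs(mix - cfg.mu) > max(0.05, 0.5 * cfg.mu):
            problems.append(f"realized mixing {mix:.3f} vs mu={cfg.mu}")
        if not problems:
            return g, part
        failures.append(f"attempt {attempt}: " + "; ".join(problems))
    raise LFRGenerationError(
        f"LFR generation failed after {cfg.max_attempts} attempts:\n"
        + "\n".join(failures))


# -- deterministic toy fixtures ---------------------------------------


def toy_graph(name: str):
    """Named deterministic graphs for oracles and examples.

    ``path_n`` / ``cycle_n`` / ``star_n`` / ``complete_n`` (n a positive
    integer), ``two_triangles`` (with its natural partition) and
    ``dyad``.  Returns an :class:`UndirectedGraph`, or a (graph,
    partition) pair for ``two_triangles``.
    """
    m = re.fullmatch(r"(path|cycle|star|complete)_(\d+)", name)
    if m:
        kind, n = m.group(1), int(m.group(2))
        if not 1 <= n <= 10_000:
            raise ValueError(f"size {n} out of bounds")
        if kind == "path":
            edges = [(i, i + 1) for i in range(n - 1)]
        elif kind == "cycle":
            if n < 3:
                raise ValueError("cycle needs at least 3 nodes")
            edges = [(i, (i + 1) % n) for i in range(n)]
        elif kind == "star":
            edges = [(0, i) for i in range(1, n)]
        else:
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        return UndirectedGraph.from_edges(edges, n=n)
    if name == "dyad":
        return UndirectedGraph.from_edges([(0, 1)], n=2)
    if name == "two_triangles":
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        return (UndirectedGraph.from_edges(edges, n=6),
                Partition(np.array([0, 0, 0, 1, 1, 1])))
    raise ValueError(f"unknown toy graph {name!r}")
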