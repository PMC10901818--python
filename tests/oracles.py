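"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: dense linear algebra, O(n^2)
pair counting, exhaustive state-space enumeration, and a time-ordered
event-driven SIR simulator.  None of it shares code with the package.
"""

from __future__ import annotations

import heapq
import itertools
import math
import random
from functools import lru_cache

import numpy as np


def dense_walk_counts(adj: np.ndarray, K: int) -> np.ndarray:
    """Columns A^k u / ||A^k u||_2 for k = 1..K, by dense matrix powers."""
    n = adj.shape[0]
    v = np.ones(n)
    cols = []
    for _ in range(K):
        v = adj @ v
        cols.append(v / np.linalg.norm(v))
    return np.column_stack(cols)


def dense_google_powers(adj: np.ndarray, K: int, alpha: float = 0.85) -> np.ndarray:
    """Columns G^k p0 with G = alpha A^T D^-1 + (1-alpha)/n 11^T, p0 uniform."""
    n = adj.shape[0]
    d = adj.sum(axis=1)
    g = alpha * adj.T / d + (1 - alpha) / n
    p = np.full(n, 1.0 / n)
    cols = []
    for _ in range(K):
        p = g @ p
        cols.append(p.copy())
    return np.column_stack(cols)


def pagerank_linear_solve(adj: np.ndarray, alpha: float = 0.85) -> np.ndarray:
    """PageRank as the solution of (I - alpha A^T D^-1) p = (1-alpha)/n 1."""
    n = adj.shape[0]
    d = adj.sum(axis=1)
    m = np.eye(n) - alpha * adj.T / d
    return np.linalg.solve(m, np.full(n, (1 - alpha) / n))


def peeling_coreness(adj_lists: list[list[int]]) -> np.ndarray:
    """k-core numbers by literal peeling: repeatedly delete min-degree nodes."""
    n = len(adj_lists)
    alive = [True] * n
    deg = [len(a) for a in adj_lists]
    core = [0] * n
    k = 0
    remaining = n
    while remaining:
        k_min = min(d for d, a in zip(deg, alive) if a)
        k = max(k, k_min)
        stack = [i for i in range(n) if alive[i] and deg[i] <= k]
        while stack:
            i = stack.pop()
            if not alive[i]:
                continue
            alive[i] = False
            core[i] = k
            remaining -= 1
            for j in adj_lists[i]:
                if alive[j]:
                    deg[j] -= 1
                    if deg[j] <= k:
                        stack.append(j)
    return np.array(core)


def brute_kendall_tau_b(a, b) -> float:
    """Tau-b by explicit O(n^2) pair counting with tie terms T and U."""
    nc = nd = t = u = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        da, db = a[i] - a[j], b[i] - b[j]
        if da == 0 and db == 0:
            continue
        if da == 0:
            t += 1
        elif db == 0:
            u += 1
        elif da * db > 0:
            nc += 1
        else:
            nd += 1
    return (nc - nd) / math.sqrt((nc + nd + t) * (nc + nd + u))


def floyd_warshall_diameter(adj: np.ndarray) -> int:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    assert np.isfinite(dist).all(), "oracle expects a connected graph"
    return int(dist.max())


def ctmc_expected_outbreak(edges: list[tuple[int, int]], n: int, seed: int,
                           beta: float, gamma: float = 1.0) -> float:
    """Exact mean final outbreak size by enumerating the SIR state space.

    State: tuple of 0=S, 1=I, 2=R per node.  Transitions S->I at rate
    beta * (#infected neighbours) and I->R at rate gamma form a DAG over
    states, so the expectation follows by memoized recursion on the
    embedded jump chain.  Feasible for a handful of nodes only.
    """
    nbrs = [[] for _ in range(n)]
    for a, b in edges:
        nbrs[a].append(b)
        nbrs[b].append(a)

    @lru_cache(maxsize=None)
    def expect(state: tuple) -> float:
        transitions = []
        for i, s in enumerate(state):
            if s == 1:
                transitions.append((gamma, i, 2))
            elif s == 0:
                k = sum(1 for j in nbrs[i] if state[j] == 1)
                if k:
                    transitions.append((beta * k, i, 1))
        if not transitions:
            return float(sum(1 for s in state if s == 2))
        total = sum(r for r, _, _ in transitions)
        acc = 0.0
        for rate, i, to in transitions:
            nxt = list(state)
            nxt[i] = to
            acc += (rate / total) * expect(tuple(nxt))
        return acc

    start = [0] * n
    start[seed] = 1
    return expect(tuple(start))


def event_driven_sir_sizes(adj_lists: list[list[int]], seed_node: int,
                           beta: float, gamma: float, runs: int,
                           seed: int) -> np.ndarray:
    """Time-ordered next-reaction SIR: full event queue, stale events dropped.

    On infection of v at time t: draw recovery at t + Exp(gamma); for each
    neighbour draw a candidate transmission at t + Exp(beta), delivered
    only if it precedes v's recovery and the target is still susceptible.
    """
    rng = random.Random(seed)
    n = len(adj_lists)
    sizes = np.empty(runs, np.int64)
    for r in range(runs):
        state = [0] * n  # 0=S 1=I 2=R
        recovery = [0.0] * n
        events: list[tuple[float, int, int, int]] = []  # (time, kind, node, src)
        state[seed_node] = 1
        recovery[seed_node] = rng.expovariate(gamma)
        heapq.heappush(events, (recovery[seed_node], 1, seed_node, -1))
        for u in adj_lists[seed_node]:
            t = rng.expovariate(beta)
            if t < recovery[seed_node]:
                heapq.heappush(events, (t, 0, u, seed_node))
        infected_total = 1
        while events:
            t, kind, node, src = heapq.heappop(events)
            if kind == 1:
                state[node] = 2
                continue
            if state[node] != 0 or state[src] != 1:
                continue  # stale transmission
            state[node] = 1
            infected_total += 1
            rec = t + rng.expovariate(gamma)
            recovery[node] = rec
            heapq.heappush(events, (rec, 1, node, -1))
            for u in adj_lists[node]:
                if state[u] == 0:
                    tt = t + rng.expovariate(beta)
                    if tt < rec:
                        heapq.heappush(events, (tt, 0, u, node))
        sizes[r] = infected_total
    return sizes
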