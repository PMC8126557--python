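"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the labelled brute-force
enumerator explores raw adjacency choices and deduplicates with networkx
isomorphism tests (no canonical forms), and the coalescence oracle simulates
the half-lazy coalescing walk directly.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def bruteforce_regular_classes(N: int, k: int) -> list[nx.Graph]:
    """All connected k-regular graphs on N vertices, one per isomorphism class.

    Enumerates every labelled k-regular graph by completing the lowest
    deficient vertex with higher-indexed deficient partners (each labelled
    graph is produced exactly once), then groups by cheap invariants and
    reduces each group with pairwise ``networkx.is_isomorphic`` checks.
    """
    adj: dict[int, set[int]] = {i: set() for i in range(N)}
    labelled: list[tuple[tuple[int, int], ...]] = []

    def rec() -> None:
        deficient = [v for v in range(N) if len(adj[v]) < k]
        if not deficient:
            labelled.append(
                tuple(sorted((u, v) for u in adj for v in adj[u] if u < v))
            )
            return
        u = deficient[0]
        need = k - len(adj[u])
        cands = [v for v in deficient if v > u and v not in adj[u]]
        for S in itertools.combinations(cands, need):
            for v in S:
                adj[u].add(v)
                adj[v].add(u)
            rec()
            for v in S:
                adj[u].remove(v)
                adj[v].remove(u)

    rec()

    buckets: dict[tuple, list[nx.Graph]] = {}
    for edges in labelled:
        g = nx.Graph()
        g.add_nodes_from(range(N))
        g.add_edges_from(edges)
        if not nx.is_connected(g):
            continue
        eigs = np.linalg.eigvalsh(nx.to_numpy_array(g))
        key = tuple(np.round(eigs, 6))
        reps = buckets.setdefault(key, [])
        if not any(nx.is_isomorphic(g, rep) for rep in reps):
            reps.append(g)
    return [g for reps in buckets.values() for g in reps]


def simulate_pair_coalescence(
    g: nx.Graph, i: int, j: int, n_reps: int, seed: int
) -> tuple[float, float]:
    """Monte Carlo mean meeting time of the half-lazy coalescing walk.

    At each step one of the two walkers (probability 1/2 each) jumps to a
    uniformly random neighbour.  Returns (mean, standard error).
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    index = {v: t for t, v in enumerate(nodes)}
    maxdeg = max(d for _, d in g.degree())
    nbrs = np.zeros((len(nodes), maxdeg), dtype=np.int64)
    deg = np.zeros(len(nodes), dtype=np.int64)
    for v in nodes:
        ns = [index[u] for u in g.neighbors(v)]
        deg[index[v]] = len(ns)
        nbrs[index[v], : len(ns)] = ns

    a = np.full(n_reps, index[i], dtype=np.int64)
    b = np.full(n_reps, index[j], dtype=np.int64)
    steps = np.zeros(n_reps, dtype=np.int64)
    alive = a != b
    while alive.any():
        n_alive = int(alive.sum())
        steps[alive] += 1
        move_a = rng.random(n_alive) < 0.5
        ia, ib = a[alive], b[alive]
        pick = rng.integers(0, 1 << 30, n_alive)
        new_a = nbrs[ia, pick % deg[ia]]
        new_b = nbrs[ib, pick % deg[ib]]
        ia = np.where(move_a, new_a, ia)
        ib = np.where(move_a, ib, new_b)
        a[alive], b[alive] = ia, ib
        alive = a != b
    return float(steps.mean()), float(steps.std(ddof=1) / np.sqrt(n_reps))
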