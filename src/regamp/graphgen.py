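"""Generation and I/O of the regular-graph populations under study.

Graphs are plain :class:`networkx.Graph` objects with vertices labelled
``0..N-1``.  The module provides

* exhaustive enumeration of connected, pairwise nonisomorphic k-regular
  graphs of a given order (vertex-augmentation search with canonical-form
  deduplication; an external graph6 stream can be dropped in as a backend
  for orders where a compiled generator is preferred),
* graph6 and edge-list I/O,
* deterministic fixture graphs (complete, cycle, seeded random regular),
* the head/mid-section/tail chain construction that glues copies of an
  amplifier-constructor block into arbitrarily long regular chains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator

import igraph as ig
import networkx as nx

__all__ = [
    "canonical_graph6",
    "certificate",
    "enumerate_regular",
    "read_graph6",
    "write_graph6",
    "read_edgelist",
    "complete_graph",
    "cycle_graph",
    "random_regular",
    "ChainSpec",
    "build_chain",
    "best_chain_spec",
    "require_simple_connected",
]


# ---------------------------------------------------------------------------
# validation and canonical forms
# ---------------------------------------------------------------------------

def require_simple_connected(g: nx.Graph, k: int | None = None) -> None:
    """Raise ``ValueError`` unless ``g`` is simple, connected (and k-regular)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if any(g.has_edge(v, v) for v in g):
        raise ValueError("graph has self-loops")
    if not nx.is_connected(g):
        raise ValueError("graph is not connected")
    if k is not None:
        bad = [v for v, d in g.degree() if d != k]
        if bad:
            raise ValueError(f"graph is not {k}-regular (vertex {bad[0]})")


def _to_igraph(g: nx.Graph) -> ig.Graph:
    idx = {v: i for i, v in enumerate(g.nodes())}
    return ig.Graph(len(idx), [(idx[u], idx[v]) for u, v in g.edges()])


def certificate(g: nx.Graph) -> bytes:
    """Canonical-form certificate: equal iff the graphs are isomorphic."""
    h = _to_igraph(g)
    h = h.permute_vertices(h.canonical_permutation())
    n = h.vcount()
    edges = sorted(tuple(sorted(e)) for e in h.get_edgelist())
    return bytes([n]) + bytes(itertools.chain.from_iterable(edges))

def canonical_graph6(g: nx.Graph) -> str:
    """graph6 string of the canonically relabelled graph."""
    h = _to_igraph(g)
    perm = h.canonical_permutation()
    n = h.vcount()
    cg = nx.Graph()
    cg.add_nodes_from(range(n))
    cg.add_edges_from((perm[u], perm[v]) for u, v in h.get_edgelist())
    return nx.to_graph6_bytes(cg, header=False).decode().strip()


# ---------------------------------------------------------------------------
# enumeration of connected k-regular graphs
# ---------------------------------------------------------------------------

def _ig_cert(n: int, edges: tuple[tuple[int, int], ...]) -> bytes:
    h = ig.Graph(n, edges)
    h = h.permute_vertices(h.canonical_permutation())
    return bytes([n]) + bytes(
        itertools.chain.from_iterable(sorted(tuple(sorted(e)) for e in h.get_edgelist()))
    )


def _augmented_regular_classes(N: int, k: int) -> list[tuple[tuple[int, int], ...]]:
    # Breadth-first vertex augmentation over isomorphism classes.  Every
    # connected k-regular graph admits a vertex ordering whose prefixes are
    # connected induced subgraphs, so it suffices to grow connected graphs of
    # maximum degree <= k one vertex at a time (the new vertex attaches to at
    # least one existing vertex) and deduplicate each level by canonical form.
    # Pruning uses necessary conditions for extendability to a connected
    # k-regular graph on N vertices: a vertex missing d stubs needs d distinct
    # future neighbours; total missing stubs fit within the future vertices'
    # capacity; a saturated graph cannot attach the remaining vertices.
    level: dict[bytes, tuple[tuple[int, ...], tuple[tuple[int, int], ...]]] = {
        _ig_cert(1, ()): ((0,), ())
    }
    for m in range(1, N):
        future = N - (m + 1)
        nxt: dict[bytes, tuple[tuple[int, ...], tuple[tuple[int, int], ...]]] = {}
        for degs, edges in level.values():
            deficient = [v for v in range(m) if degs[v] < k]
            for s in range(1, k + 1):
                for S in itertools.combinations(deficient, s):
                    ndegs = list(degs) + [s]
                    for v in S:
                        ndegs[v] += 1
                    missing = (m + 1) * k - sum(ndegs)
                    if future == 0:
                        if missing != 0:
                            continue
                    else:
                        if missing == 0 or missing > k * future:
                            continue
                        if any(k - d > future for d in ndegs):
                            continue
                        if missing < k * future - future * (future - 1):
                            continue
                    nedges = edges + tuple((v, m) for v in S)
                    c = _ig_cert(m + 1, nedges)
                    if c not in nxt:
                        nxt[c] = (tuple(ndegs), nedges)
        level = nxt
    return [edges for _, edges in level.values()]


def enumerate_regular(
    N: int, k: int, backend: Iterable[str] | str | None = None
) -> Iterator[nx.Graph]:
    """Yield every connected nonisomorphic k-regular graph of order ``N``.

    Graphs are produced exactly once each, in a deterministic canonical order
    (sorted by canonical graph6 string).  ``backend`` may supply an external
    graph6 stream (path or iterable of lines, e.g. produced by ``geng``),
    which is validated, deduplicated and re-ordered the same way.
    """
    if N <= k:
        raise ValueError(f"infeasible: need N > k (got N={N}, k={k})")
    if (N * k) % 2:
        raise ValueError(f"parity violation: N*k must be even (got N={N}, k={k})")

    if backend is not None:
        graphs = {}
        for g in read_graph6(backend):
            require_simple_connected(g, k)
            if g.number_of_nodes() != N:
                raise ValueError("backend graph has wrong order")
            graphs[certificate(g)] = g
        for g6 in sorted(canonical_graph6(g) for g in graphs.values()):
            yield nx.from_graph6_bytes(g6.encode())
        return

    out = []
    for edges in _augmented_regular_classes(N, k):
        g = nx.Graph()
        g.add_nodes_from(range(N))
        g.add_edges_from(edges)
        out.append((canonical_graph6(g), g))
    out.sort(key=lambda t: t[0])
    for g6, _ in out:
        yield nx.from_graph6_bytes(g6.encode())


# ---------------------------------------------------------------------------
# graph6 / edge-list I/O
# ---------------------------------------------------------------------------

def read_graph6(source: Iterable[str] | str) -> Iterator[nx.Graph]:
    """Read graphs from a graph6 file path or an iterable of graph6 lines."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = [str(line).strip() for line in source]
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(">>graph6<<"):
            line = line.replace(">>graph6<<", "")
            if not line:
                continue
        try:
            yield nx.from_graph6_bytes(line.encode())
        except (nx.NetworkXError, ValueError) as exc:
            raise ValueError(f"malformed graph6 on line {ln}: {exc}") from exc


def write_graph6(graphs: Iterable[nx.Graph], path: str | None = None) -> list[str]:
    """Encode graphs as graph6 lines; optionally write them to ``path``."""
    lines = [nx.to_graph6_bytes(g, header=False).decode().strip() for g in graphs]
    if path is not None:
        with open(path, "w") as fh:
            for line in lines:
                fh.write(line + "\n")
    return lines


def read_edgelist(source: Iterable[str] | str) -> nx.Graph:
    """Read a single graph from a two-column whitespace edge list (0-based)."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = list(source)
    g = nx.Graph()
    for ln, line in enumerate(lines, start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if len(parts) < 2:
            raise ValueError(f"malformed edge list on line {ln}: {line!r}")
        u, v = int(parts[0]), int(parts[1])
        g.add_edge(u, v)
    g.add_nodes_from(range(max(g.nodes(), default=-1) + 1))
    return g


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def complete_graph(N: int) -> nx.Graph:
    if N < 2:
        raise ValueError("complete graph needs N >= 2")
    return nx.complete_graph(N)


def cycle_graph(N: int) -> nx.Graph:
    if N < 3:
        raise ValueError("cycle graph needs N >= 3")
    return nx.cycle_graph(N)


def random_regular(N: int, k: int, seed: int, max_tries: int = 100) -> nx.Graph:
    """Seeded connected random k-regular graph (reproducible for fixed seed)."""
    for t in range(max_tries):
        g = nx.random_regular_graph(k, N, seed=seed + t)
        if nx.is_connected(g):
            return g
    raise RuntimeError(f"no connected {k}-regular graph of order {N} after {max_tries} tries")


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

@dataclass
class ChainSpec:
    """Recipe for chaining copies of a k-regular block into a longer k-regular graph.

    The first block (head) drops ``head_cut``, the last block (tail) drops
    ``tail_cut`` and every interior block (mid-section) drops both
    ``mid_cuts`` edges (defaulting to head and tail cut).  Consecutive blocks
    are re-joined by two connector edges pairing the dangling (degree-deficient)
    vertices; ``connectors`` lists local index pairs ``(left_block_vertex,
    right_block_vertex)``.  The default pairing joins the head-cut endpoints
    ``(a, b)`` of the left block to the tail-cut endpoints ``(c, d)`` of the
    right block as ``a-d`` and ``b-c``.
    """

    block: nx.Graph
    head_cut: tuple[int, int]
    tail_cut: tuple[int, int]
    n_blocks: int = 2
    mid_cuts: tuple[tuple[int, int], tuple[int, int]] | None = None
    connectors: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.head_cut = tuple(sorted(self.head_cut))
        self.tail_cut = tuple(sorted(self.tail_cut))
        if self.mid_cuts is None:
            self.mid_cuts = (self.head_cut, self.tail_cut)
        if self.connectors is None:
            a, b = self.head_cut
            c, d = self.tail_cut
            self.connectors = ((a, d), (b, c))


def build_chain(spec: ChainSpec) -> nx.Graph:
    """Build the chain graph described by ``spec`` and validate regularity."""
    block = spec.block
    n = block.number_of_nodes()
    degrees = {d for _, d in block.degree()}
    if len(degrees) != 1:
        raise ValueError("chain block must be regular")
    k = degrees.pop()
    if spec.n_blocks < 2:
        raise ValueError("chain needs at least a head and a tail (n_blocks >= 2)")
    for cut in (spec.head_cut, spec.tail_cut, *spec.mid_cuts):
        if not block.has_edge(*cut):
            raise ValueError(f"cut edge {cut} not present in block")

    g = nx.Graph()
    M = spec.n_blocks
    for b in range(M):
        off = b * n
        g.add_nodes_from(off + v for v in range(n))
        drops = set()
        if b < M - 1:
            drops.add(spec.mid_cuts[0] if 0 < b else spec.head_cut)
        if b > 0:
            drops.add(spec.mid_cuts[1] if b < M - 1 else spec.tail_cut)
        for u, v in block.edges():
            if tuple(sorted((u, v))) in drops:
                continue
            g.add_edge(off + u, off + v)
    for b in range(M - 1):
        for left, right in spec.connectors:
            u, v = b * n + left, (b + 1) * n + right
            if g.has_edge(u, v):
                raise ValueError(f"connector would duplicate edge ({u}, {v})")
            g.add_edge(u, v)

    for v, d in g.degree():
        if d != k:
            raise ValueError(
                f"chain construction broke regularity at vertex {v} (degree {d} != {k})"
            )
    if not nx.is_connected(g):
        raise ValueError("chain construction yields a disconnected graph")
    return g


def best_chain_spec(block: nx.Graph, n_blocks: int = 2) -> "ChainSpec":
    """Search cut/connector choices maximizing the perturbed N_eff of the chain.

    The figure labelings that fix the published cut edges are a presentation
    convention, so the concrete choice is recovered by enumerating all
    symmetry-inequivalent (head cut, tail cut, pairing) combinations, scoring
    each resulting chain by the best effective population size reachable by
    the single-edge perturbation, and returning the argmax.
    """
    from .coalescence import perturb_search

    edges = [tuple(sorted(e)) for e in block.edges()]
    seen: set[bytes] = set()
    best: tuple[float, ChainSpec] | None = None
    for head_cut in edges:
        for tail_cut in edges:
            a, b = head_cut
            c, d = tail_cut
            for pairing in (((a, d), (b, c)), ((a, c), (b, d))):
                try:
                    spec = ChainSpec(
                        block, head_cut, tail_cut, n_blocks=n_blocks, connectors=pairing
                    )
                    chain = build_chain(spec)
                except ValueError:
                    continue
                cert = certificate(chain)
                if cert in seen:
                    continue
                seen.add(cert)
                outcome = perturb_search(chain, n_remove=1)
                score = outcome.best_n_eff if outcome.best_n_eff is not None else -1.0
                if best is None or score > best[0]:
                    best = (score, spec)
    if best is None:
        raise ValueError("no feasible chain construction found for this block")
    return best[1]
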