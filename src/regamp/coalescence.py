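"""Coalescing-random-walk machinery for weak-selection amplification.

Two half-lazy random walkers (at each update step one of the two, chosen with
probability 1/2, moves to a uniformly random neighbour) coalesce when they
first occupy the same vertex.  The expected pairwise coalescence times
``tau_ij`` solve the linear system

    tau_ij = 1 + 1/2 * sum_k (p_ik tau_jk + p_jk tau_ik),   tau_ii = 0,

with step probabilities ``p_ij = e_ij / k_i``.  From these, the remeeting
time of vertex i is ``tau_i = 1 + sum_j p_ij tau_ij`` and the effective
population size is the degree-weighted mean ``N_eff = sum_i pi_i tau_i``
with relative degrees ``pi_i = k_i / sum_j k_j``.  For death-birth updating,
``N_eff > N`` certifies amplification of weak selection; k-regular graphs
always have ``N_eff = N`` (isothermal theorem), but removing an edge at the
vertex of largest remeeting time can push ``N_eff`` above ``N`` -- the
perturbation search implemented by :func:`perturb_search`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "CoalescenceSummary",
    "PerturbationOutcome",
    "RemovalRecord",
    "coalescence_times",
    "remeeting_times",
    "effective_population_size",
    "remeeting_statistics",
    "first_order_delta",
    "perturb_search",
]

_DENSE_LIMIT = 32  # order above which the pair system is solved sparsely
_RESIDUAL_TOL = 1e-10
_TIE_RTOL = 1e-9
_CONSTRUCTOR_MARGIN = 1e-9


@dataclass
class CoalescenceSummary:
    """Pairwise coalescence times and derived per-vertex quantities."""

    graph: nx.Graph
    tau_pair: np.ndarray      # (N, N) symmetric, zero diagonal
    tau_remeet: np.ndarray    # (N,) remeeting times
    pi: np.ndarray            # (N,) relative degrees, sums to 1
    n_eff: float              # degree-weighted mean remeeting time

    @property
    def order(self) -> int:
        return self.tau_pair.shape[0]

    def identity_residual(self) -> float:
        """|sum_i pi_i^2 tau_i - 1|; zero for every connected graph."""
        return abs(float(self.pi**2 @ self.tau_remeet) - 1.0)


def _pair_system(P: np.ndarray | sp.spmatrix, n: int, dense: bool):
    # vec(T) row-major; T = J + (P T + T P^T)/2 off the diagonal, T_ii = 0.
    if dense:
        I = np.eye(n)
        M = np.eye(n * n) - 0.5 * (np.kron(P, I) + np.kron(I, P))
        diag_states = np.arange(n) * n + np.arange(n)
        M[diag_states, :] = 0.0
        M[diag_states, diag_states] = 1.0
        rhs = np.ones(n * n)
        rhs[diag_states] = 0.0
        return M, rhs
    I = sp.identity(n, format="csr")
    halfstep = 0.5 * (sp.kron(P, I, format="csr") + sp.kron(I, P, format="csr"))
    mask = np.ones(n * n)
    mask[np.arange(n) * n + np.arange(n)] = 0.0
    M = sp.identity(n * n, format="csr") - sp.diags(mask) @ halfstep
    rhs = mask.copy()
    return M.tocsr(), rhs


def coalescence_times(g: nx.Graph) -> CoalescenceSummary:
    """Solve for tau_ij and derive remeeting times, pi and N_eff.

    Raises ``ValueError`` on disconnected input, for which the coalescence
    times diverge and the linear system is singular.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("coalescence needs at least two vertices")
    if not nx.is_connected(g):
        raise ValueError("coalescence undefined (singular system): graph is disconnected")

    nodes = sorted(g.nodes())
    A = nx.to_numpy_array(g, nodelist=nodes)
    deg = A.sum(axis=1)
    P = A / deg[:, None]

    dense = n <= _DENSE_LIMIT
    if dense:
        M, rhs = _pair_system(P, n, dense=True)
        x = np.linalg.solve(M, rhs)
    else:
        M, rhs = _pair_system(sp.csr_matrix(P), n, dense=False)
        x = spla.spsolve(M, rhs)

    resid = np.abs(M @ x - rhs).max()
    scale = max(1.0, np.abs(x).max())
    if resid > _RESIDUAL_TOL * scale:
        raise RuntimeError(f"pair-time linear solve residual too large: {resid:.2e}")

    T = x.reshape(n, n)
    T = 0.5 * (T + T.T)
    tau_remeet = 1.0 + (P * T).sum(axis=1)
    pi = deg / deg.sum()
    n_eff = float(pi @ tau_remeet)
    return CoalescenceSummary(graph=g, tau_pair=T, tau_remeet=tau_remeet, pi=pi, n_eff=n_eff)


def remeeting_times(summary: CoalescenceSummary) -> np.ndarray:
    """Per-vertex remeeting times tau_i = 1 + sum_j p_ij tau_ij."""
    return summary.tau_remeet


def effective_population_size(summary: CoalescenceSummary) -> float:
    """Effective population size N_eff = sum_i pi_i tau_i."""
    return summary.n_eff


def remeeting_statistics(summary: CoalescenceSummary) -> tuple[float, float, float]:
    """(mean, variance, max) of the remeeting times; mean equals N on regular graphs."""
    tau = summary.tau_remeet
    return float(tau.mean()), float(tau.var()), float(tau.max())


def first_order_delta(
    summary: CoalescenceSummary, removed_edges: tuple[tuple[int, int], ...]
) -> float:
    """First-order estimate of the N_eff shift: -sum_i dpi_i tau_i.

    Uses the unperturbed remeeting times and the exact post-removal relative
    degrees; valid for small perturbations of a regular graph.
    """
    nodes = sorted(summary.graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    deg = np.array([summary.graph.degree(v) for v in nodes], dtype=float)
    new_deg = deg.copy()
    for u, v in removed_edges:
        new_deg[index[u]] -= 1
        new_deg[index[v]] -= 1
    dpi = new_deg / new_deg.sum() - deg / deg.sum()
    return float(-(dpi @ summary.tau_remeet))


# ---------------------------------------------------------------------------
# perturbation search
# ---------------------------------------------------------------------------

@dataclass
class RemovalRecord:
    """Outcome of one candidate edge removal at a pivot vertex."""

    edges: tuple[tuple[int, int], ...]
    connected: bool
    n_eff: float | None
    delta_first_order: float


@dataclass
class PerturbationOutcome:
    """Result of the max-remeeting-vertex edge-removal search on one graph."""

    base: nx.Graph
    summary: CoalescenceSummary
    pivots: list[int]
    per_removal: list[RemovalRecord] = field(default_factory=list)

    @property
    def order(self) -> int:
        return self.base.number_of_nodes()

    @property
    def best_n_eff(self) -> float | None:
        vals = [r.n_eff for r in self.per_removal if r.n_eff is not None]
        return max(vals) if vals else None

    @property
    def best_removal(self) -> RemovalRecord | None:
        recs = [r for r in self.per_removal if r.n_eff is not None]
        return max(recs, key=lambda r: r.n_eff) if recs else None

    @property
    def is_constructor(self) -> bool:
        best = self.best_n_eff
        return best is not None and best > self.order + _CONSTRUCTOR_MARGIN


def _pivot_vertices(summary: CoalescenceSummary) -> list[int]:
    nodes = sorted(summary.graph.nodes())
    tau = summary.tau_remeet
    tmax = tau.max()
    return [nodes[i] for i in range(len(nodes)) if tau[i] >= tmax * (1.0 - _TIE_RTOL)]


def _evaluate_removal(
    g: nx.Graph, edges: tuple[tuple[int, int], ...], base: CoalescenceSummary
) -> RemovalRecord:
    h = g.copy()
    h.remove_edges_from(edges)
    delta = first_order_delta(base, edges)
    if not nx.is_connected(h):
        return RemovalRecord(edges=edges, connected=False, n_eff=None, delta_first_order=delta)
    n_eff = coalescence_times(h).n_eff
    return RemovalRecord(edges=edges, connected=True, n_eff=n_eff, delta_first_order=delta)


def perturb_search(
    g: nx.Graph, n_remove: int = 1, mode: str = "simultaneous"
) -> PerturbationOutcome:
    """Remove edge(s) at the vertex (or tied vertices) of largest remeeting time.

    ``n_remove=1`` tries every connectivity-preserving single-edge removal at
    a pivot; ``n_remove=2`` removes unordered pairs of pivot edges, either
    both at once (``mode="simultaneous"``) or one after the other with
    re-identification of the pivot in between (``mode="sequential"``).
    Removals that disconnect the graph are recorded but carry no N_eff.
    """
    degrees = {d for _, d in g.degree()}
    if len(degrees) != 1:
        raise ValueError("perturbation method is defined for regular graphs only")
    if n_remove not in (1, 2):
        raise ValueError("n_remove must be 1 or 2")
    if mode not in ("simultaneous", "sequential"):
        raise ValueError("mode must be 'simultaneous' or 'sequential'")

    base = coalescence_times(g)
    pivots = _pivot_vertices(base)
    outcome = PerturbationOutcome(base=g, summary=base, pivots=pivots)

    seen: set[tuple[tuple[int, int], ...]] = set()
    for v in pivots:
        incident = [tuple(sorted((v, u))) for u in g.neighbors(v)]
        if n_remove == 1:
            candidates = [(e,) for e in incident]
        elif mode == "simultaneous":
            candidates = [tuple(sorted(pair)) for pair in itertools.combinations(incident, 2)]
        else:
            candidates = []
            for e1 in incident:
                h = g.copy()
                h.remove_edge(*e1)
                if not nx.is_connected(h):
                    continue
                inner = coalescence_times(h)
                for w in _pivot_vertices(inner):
                    for e2 in (tuple(sorted((w, u))) for u in h.neighbors(w)):
                        candidates.append(tuple(sorted((e1, e2))))
        for edges in candidates:
            if edges in seen:
                continue
            seen.add(edges)
            outcome.per_removal.append(_evaluate_removal(g, edges, base))
    return outcome
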