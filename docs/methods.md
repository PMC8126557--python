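# Methods

## Model

Evolutionary dynamics on a graph G = (V, E): vertices are individuals,
edges are interaction partners. All graphs handled by the analysis entry
points are simple, undirected, unweighted and connected, with 0-based
vertex labels. Under death–birth (dB) updating a uniformly random
individual dies (probability 1/N) and a neighbour is chosen to reproduce
into the vacancy with probability proportional to fitness (r for mutants,
1 for residents). The state of the population is the mutant-occupied vertex
set; fixation and extinction are the absorbing states.

## Coalescence machinery

Pairwise coalescence times of the half-lazy coalescing random walk (one of
the two walkers moves per step, each with probability 1/2, to a uniformly
random neighbour) solve the C(N,2) linear system

    τ_ij = 1 + ½ Σ_k (p_ik τ_jk + p_jk τ_ik)  (i ≠ j),  τ_ii = 0,

with step probabilities p_ij = e_ij/k_i. We solve the equivalent n²-state
system in Kronecker form, vec(T) = vec(J) + ½ (P⊗I + I⊗P) vec(T) with the
diagonal rows pinned to zero: assembly is pure matrix algebra, the solution
is automatically symmetric, and the same code path covers dense
(N ≤ 32, LAPACK) and sparse (larger chains, SuperLU) regimes. The solve is
rejected if the residual exceeds 1e-10 (relative to the solution magnitude).
Derived quantities: remeeting times τ_i = 1 + Σ_j p_ij τ_ij, relative
degrees π_i = k_i/Σk_j, effective population size N_eff = Σ π_i τ_i. Two
exact identities are enforced as invariants in the tests: Σ π_i² τ_i = 1 on
every connected graph and N_eff = N (equivalently mean τ_i = N) on every
regular graph; both hold at ~1e-15 and are sensitive to any assembly error.

### Perturbation search

For a k-regular input, all vertices within relative tolerance 1e-9 of the
maximal remeeting time are pivots. For `n_remove=1` each pivot-incident
edge is removed in turn; for `n_remove=2` unordered pairs of pivot edges
are removed, by default simultaneously. A `sequential` mode instead removes
one edge, re-solves, re-identifies the pivot and removes a second edge
there; the published counts of two-edge constructors do not state which
convention was used, so both are available (default: simultaneous).
Removals that disconnect the graph are recorded but not scored: the
coalescence system is singular on disconnected graphs, so such removals
cannot produce a finite N_eff and are treated as inadmissible rather than
as failures. A graph is an **amplifier constructor** when some admissible
removal yields N_eff > N + 1e-9; the 1e-9 margin is far below the smallest
observed constructor excess (~1.4e-4) and far above solver error (~1e-12).

The first-order diagnostic ΔN_eff ≈ −Σ_i Δπ_i τ_i combines base-graph
remeeting times with exact post-removal relative degrees. Note that it
vanishes identically on graphs with constant τ_i (e.g. vertex-transitive
graphs), where the true ΔN_eff is second order; it is a search heuristic,
not a bound.

## Exact fixation probabilities

ρ_G(r) is computed by solving the absorbing Markov chain on mutant subsets
encoded as bitmasks: x_S = Σ_T P(S→T) x_T with x_∅ = 0, x_V = 1; ρ_G(r)
averages the N single-mutant states. Every dB event changes the mutant
count by at most one, so with states grouped by mutant count the
2^N − 2-state transient system is block tridiagonal and its diagonal
blocks are diagonal. The solver exploits this with a dense
Schur-complement sweep over the mutant-count levels (eliminating from
fixation down to the singleton level), which costs O(Σ_m C(N,m)³) time and
O(max_m C(N,m)²) working memory — orders of magnitude below generic
sparse LU, whose fill-in on this state graph is severe (a naive
factorization at N = 14 takes ~40 s and gigabytes; the level sweep ~7 s
and ~0.6 GB). The per-level LU factors are cached, so two steps of
iterative refinement cost only triangular solves and push the residual to
~1e-15: single-edge perturbations open amplification windows whose ratio
amplitude is only ~1e-9, so machine-precision solutions are required, and
for the same reason the complete-graph and cycle baselines are evaluated
in expm1/log1p form (the raw formulas lose half their digits to
cancellation near r = 1). The solver refuses N above a default cap of 16
unless overridden; memory for the middle level (C(N, N/2)² doubles) is
the practical ceiling.

### Locating r_max

The ratio ρ_G/ρ_N is evaluated on an equidistant 13-point grid on
[1, 1 + w]. The window w starts at 0.01 and is adapted geometrically in
both directions: shrunk (÷4, down to 8 scales) until the sign of the
deviation just above r = 1 is resolved outside a 1e-11 noise band — the
window of the perturbed quartic-11 graph (~8e-4) closes before the first
grid step of the default window — and widened (×2) until the ratio has
fallen below 1. The crossing is refined by bisection (to 1e-10) on the
Lagrange interpolant through the final grid (degree = grid size − 1,
evaluated barycentrically). Classification: `transient_amplifier` when the
deviation is positive with a bracketed crossing; `transient_suppressor`
when it is negative but the ratio exceeds 1 somewhere below r = 1 (lower
window scan); `neutral_equivalent` when no deviation is resolved at any
scale (complete graphs); `other` for the remaining shapes.

## Enumeration of regular graphs

Connected k-regular graphs of order N are generated by breadth-first
vertex augmentation over isomorphism classes: every connected graph admits
a construction order in which each added vertex attaches to at least one
earlier vertex, so it suffices to grow connected graphs of maximum degree
≤ k one vertex at a time and deduplicate each level by canonical form
(igraph/BLISS canonical permutations; the certificate is the canonically
relabelled edge list). Levels are pruned by necessary extendability
conditions: a vertex missing d stubs needs d distinct future neighbours
(d ≤ N − m), total missing stubs must fit within k(N − m), a saturated
proper subgraph can never reconnect, and near the top the future subgraph
must be able to absorb the remaining stubs. The final stream is sorted by
canonical graph6 string, making runs reproducible and the output order a
stable contract. Desk-scale censuses (cubic N ≤ 16: 85/509/4060 classes;
quartic N ≤ 11: 265) complete in seconds to ~2 minutes on one CPU; an
external graph6 stream (e.g. from `geng`) can be dropped in as the
enumeration backend for larger orders and is validated, deduplicated and
reordered identically. A brute-force labelled enumerator with
networkx-isomorphism deduplication serves as the independent oracle at
N ≤ 8 in the tests.

## Chains

Amplifier constructors can be concatenated into arbitrarily long k-regular
chains: the head block drops one designated edge, the tail block another,
interior blocks both, and consecutive blocks are rejoined by two connector
edges pairing the dangling vertices. Published examples reference figure
labelings that are not recoverable from the text, so `ChainSpec` makes the
cut edges and connector pairing explicit, and `best_chain_spec` enumerates
all symmetry-inequivalent (head cut, tail cut, pairing) choices of a block
— deduplicated by canonical form — and returns the one maximizing the
perturbed N_eff of the resulting chain. Chains built this way from the
cubic-12 constructor remain constructors with N_eff/N decaying toward 1 as
mid-sections are added (isothermal limit), which the tests assert for 2–5
blocks.

## Spectral analysis

The normalized Laplacian L = I − D^{−1/2} A D^{−1/2} is diagonalized
densely (symmetric eigensolver); eigenvalues within 1e-9 outside [0, 2]
are clipped. The smoothed spectral density convolves the spectrum with a
Gaussian kernel of width σ = 1/(3N) — the kernel exponent is negative, as
in the sources defining the construction, although one printed form omits
the sign — evaluated on a fixed grid of 2001 points on [0, 2]. The
spectral distance is the L1 difference of two densities over [0, 2] by
trapezoidal quadrature (a pseudometric; kernel mass outside [0, 2] is not
renormalized). Family densities are arithmetic means of member densities;
the aggregation used for the published family curves is not stated, so
only orderings of family distances are asserted, not their magnitudes.
The von Neumann entropy is the base-2 Shannon entropy of ν_i = λ_i/N
(0 log 0 = 0). The Kesten–McKay law for the normalized Laplacian of random
k-regular graphs is provided in two normalizations: the default integrates
to one; `normalized=False` reproduces the commonly printed form
√(4(k−1) − k²(1−x)²)/(2πk(2−x)x), whose total mass is 1/k because the
substitution x = 1 − μ/k from the adjacency law contributes a Jacobian
factor k. The remeeting-time bound τ_i ≤ (N−1)/λ₂ + (2N−1)/N is checked
with slack reporting; it is tight exactly on complete graphs.

## Threshold classifier

Within one (N, k) census slice, predict "constructor" iff max τ_i ≥ the
smallest constructor max τ_i AND λ₂ ≤ the largest constructor λ₂, both
inclusive, so recall is 100% by construction; precision and accuracy are
reported in percent. A caveat discovered on the cubic N=16 census: seven
non-constructors share the threshold λ₂ *exactly* (equal eigenvalues, ties
at 1e-15), so the false-positive count is tie-convention-dependent — 144
inclusive, 137 with exact ties excluded — and any count inside that
bracket is an artifact of eigensolver round-off at the degenerate
boundary. The tests therefore pin the robust quantities (TP, FN) exactly
and bracket the tie-sensitive ones.

## Survey pipeline

`run_census` streams the canonical enumeration order through
coalescence → perturbation → spectral (→ optional r_max for constructors
up to a configurable order cap, default 14, since the fixation stage is
exponential in N), emitting one record per graph. Output order equals the
canonical stream order, making reruns byte-identical; with an output
directory, records are appended as computed and an interrupted run resumes
from the rows already present. Counts are plain integers throughout.
`export_figure_data` writes the scatter tables (var τ / max τ / λ₂ /
entropy / r_max against N_eff/N) and the family densities and distances;
the constructor-family export is skipped with a warning when a slice has
no constructors (e.g. any k ≥ 6 slice tested).

## Synthetic inputs and scope of the tests

The package generates all of its own inputs: exhaustive censuses (the
actual study population — not a sample), deterministic fixtures (complete
graphs, cycles, seeded connected random regular graphs) and chain
constructions. Because the censuses are exhaustive, passing census tests
is evidence about the full finite universe of small cubic/quartic graphs,
not about an approximation to it; what the desk-scale suite does *not*
probe are the larger orders (cubic 18–22, quartic 12–16, quintic 14),
which the same code supports given an external enumeration backend and
more CPU time. Default suite problem sizes: censuses up to cubic N=16 and
quartic N=11, fixation solves up to 2^14 states (r_max association on the
seven cubic-14 constructors), chains up to 60 vertices, Monte Carlo walk
oracles at 2×10^5 replicates.

## Known limitations

- Exact fixation is capped (by default) at N = 16; beyond that the
  2^N-state chain is impractical on one machine.
- Enumeration in pure Python tops out around cubic N=16 / quartic N=12 at
  interactive timescales; larger censuses need the graph6 backend hook.
- The two-edge removal convention behind the published parenthetical
  counts is ambiguous; both implemented modes are available but the counts
  themselves are not asserted.
- Disconnecting removals are defined as inadmissible rather than scored;
  this is the only choice consistent with the coalescence formalism, but
  it is a convention where the source is silent.
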