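import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regamp import (
    coalescence_times,
    complete_graph,
    cycle_graph,
    effective_population_size,
    first_order_delta,
    perturb_search,
    random_regular,
    remeeting_statistics,
    remeeting_times,
)

from oracles import simulate_pair_coalescence


class TestClosedForms:
    def test_k2_single_step(self):
        s = coalescence_times(complete_graph(2))
        assert s.tau_pair[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("N", [3, 5, 8, 12])
    def test_complete_graph_pair_times(self, N):
        """K_N: tau_ij = N - 1 for all pairs, tau_i = N."""
        s = coalescence_times(complete_graph(N))
        off = s.tau_pair[~np.eye(N, dtype=bool)]
        assert np.allclose(off, N - 1, atol=1e-10)
        assert np.allclose(remeeting_times(s), N, atol=1e-10)

    @pytest.mark.parametrize("N", [4, 7, 10])
    def test_cycle_pair_times_are_gamblers_ruin(self, N):
        """C_N: tau_ij = d(N-d) with d the cycle distance."""
        s = coalescence_times(cycle_graph(N))
        for i in range(N):
            for j in range(N):
                d = min(abs(i - j), N - abs(i - j))
                assert s.tau_pair[i, j] == pytest.approx(d * (N - d), abs=1e-9)

    @pytest.mark.parametrize("N", [4, 9])
    def test_vertex_transitive_statistics(self, N):
        for g in (complete_graph(N), cycle_graph(N)):
            mean, var, tmax = remeeting_statistics(coalescence_times(g))
            assert mean == pytest.approx(N, abs=1e-9)
            assert var == pytest.approx(0.0, abs=1e-9)
            assert tmax == pytest.approx(N, abs=1e-9)


@settings(max_examples=12, derandomize=True, deadline=None)
@given(
    st.sampled_from([(8, 3), (10, 3), (12, 3), (9, 4), (11, 4), (10, 5)]),
    st.integers(min_value=0, max_value=50),
)
def test_regular_graph_invariants(nk, seed):
    """Sum pi_i^2 tau_i = 1, mean tau_i = N and N_eff = N on regular graphs."""
    N, k = nk
    g = random_regular(N, k, seed=seed)
    s = coalescence_times(g)
    assert s.identity_residual() < 1e-9
    assert s.tau_remeet.mean() == pytest.approx(N, abs=1e-9)
    assert effective_population_size(s) == pytest.approx(N, abs=1e-9)
    assert np.allclose(s.tau_pair, s.tau_pair.T, atol=1e-10)
    assert s.tau_pair.min() >= 0.0


def test_identity_condition_holds_for_irregular_graphs():
    g = complete_graph(4)
    g.remove_edge(0, 1)
    s = coalescence_times(g)
    assert s.identity_residual() < 1e-9
    assert s.n_eff < 4.0  # removing an edge of K4 shrinks N_eff


def test_sparse_and_dense_paths_agree():
    g = random_regular(36, 3, seed=7)  # order above the dense cutoff
    s = coalescence_times(g)
    assert s.identity_residual() < 1e-9
    assert s.n_eff == pytest.approx(36, abs=1e-8)


def test_disconnected_graph_is_rejected():
    g = nx.disjoint_union(complete_graph(3), complete_graph(3))
    with pytest.raises(ValueError, match="singular"):
        coalescence_times(g)


@pytest.mark.parametrize(
    "g,i,j",
    [
        (cycle_graph(5), 0, 2),
        (nx.house_graph(), 0, 4),
    ],
)
def test_pair_times_match_walk_simulation(g, i, j):
    """Linear-system times agree with direct simulation of the half-lazy walk."""
    s = coalescence_times(g)
    nodes = sorted(g.nodes())
    expected = s.tau_pair[nodes.index(i), nodes.index(j)]
    mean, se = simulate_pair_coalescence(g, i, j, n_reps=200_000, seed=11)
    assert abs(mean - expected) < 5 * se


class TestPerturbation:
    def test_complete_graph_is_not_a_constructor(self):
        out = perturb_search(complete_graph(5))
        assert not out.is_constructor
        assert out.best_n_eff < 5.0
        # K5 is vertex-transitive: every vertex ties at the pivot
        assert len(out.pivots) == 5

    def test_nonregular_input_rejected(self):
        g = complete_graph(4)
        g.remove_edge(0, 1)
        with pytest.raises(ValueError, match="regular"):
            perturb_search(g)

    def test_bridgeless_graph_scores_every_removal(self):
        out = perturb_search(nx.circular_ladder_graph(3))  # the 3-prism
        for rec in out.per_removal:
            assert rec.connected
            assert rec.n_eff is not None

    def test_bridge_removal_recorded_without_score(self):
        # smallest cubic graph with a bridge: two K4-minus-edge blocks, each
        # closed off by an apex vertex, joined apex-to-apex
        block = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (4, 2), (4, 3)]
        g = nx.Graph()
        g.add_edges_from(block)
        g.add_edges_from([(u + 5, v + 5) for u, v in block])
        g.add_edge(4, 9)  # the bridge; every vertex now has degree 3
        assert all(d == 3 for _, d in g.degree())
        out = perturb_search(g)
        bridge_recs = [r for r in out.per_removal if (4, 9) in r.edges]
        assert bridge_recs
        assert all(not r.connected and r.n_eff is None for r in bridge_recs)
        # the apexes are the pivots by symmetry, and the two non-bridge
        # removals at each stay connected and get scored
        scored = [r for r in out.per_removal if r.n_eff is not None]
        assert scored

    def test_two_edge_modes_both_run(self):
        g = random_regular(10, 4, seed=3)
        for mode in ("simultaneous", "sequential"):
            out = perturb_search(g, n_remove=2, mode=mode)
            assert out.per_removal
            for rec in out.per_removal:
                assert len(rec.edges) == 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            perturb_search(complete_graph(4), n_remove=3)
        with pytest.raises(ValueError):
            perturb_search(complete_graph(4), mode="bogus")


class TestFirstOrderDelta:
    def test_noop_removal_is_zero(self):
        s = coalescence_times(complete_graph(5))
        assert first_order_delta(s, ()) == 0.0

    def test_vertex_transitive_estimate_vanishes(self):
        # on K5 every tau_i is equal, so -sum dpi_i tau_i = -tau * sum dpi_i = 0:
        # the N_eff drop under removal is a purely second-order effect
        out = perturb_search(complete_graph(5))
        for rec in out.per_removal:
            assert rec.delta_first_order == pytest.approx(0.0, abs=1e-12)
            assert rec.n_eff - 5.0 < 0

    def test_sign_agreement_on_quartic11_constructor(self, quartic11_census):
        g6 = quartic11_census.constructors().iloc[0]["graph6"]
        g = nx.from_graph6_bytes(g6.encode())
        out = perturb_search(g)
        for rec in out.per_removal:
            if rec.n_eff is None:
                continue
            exact = rec.n_eff - 11.0
            assert np.sign(rec.delta_first_order) == np.sign(exact)
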