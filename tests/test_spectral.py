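import networkx as nx
import numpy as np
import pytest
from scipy.integrate import quad

from regamp import (
    FamilySpectral,
    SpectralSummary,
    coalescence_times,
    complete_graph,
    cycle_graph,
    enumerate_regular,
    kesten_mckay_density,
    normalized_laplacian_spectrum,
    remeeting_bound,
    smoothed_density,
    spectral_distance,
    von_neumann_entropy,
)
from regamp.spectral import default_grid


class TestSpectrum:
    def test_k2(self):
        assert np.allclose(normalized_laplacian_spectrum(complete_graph(2)), [0.0, 2.0])

    @pytest.mark.parametrize("N", [3, 5, 9])
    def test_complete_graph_spectrum(self, N):
        eigs = normalized_laplacian_spectrum(complete_graph(N))
        expected = np.array([0.0] + [N / (N - 1)] * (N - 1))
        assert np.allclose(eigs, expected, atol=1e-9)
        assert eigs[1] == pytest.approx(N / (N - 1))

    @pytest.mark.parametrize("N", [4, 7, 12])
    def test_cycle_spectrum_is_circulant(self, N):
        eigs = normalized_laplacian_spectrum(cycle_graph(N))
        expected = np.sort(1.0 - np.cos(2 * np.pi * np.arange(N) / N))
        assert np.allclose(eigs, expected, atol=1e-9)

    def test_basic_invariants_and_regular_equivalence(self):
        g = nx.petersen_graph()
        eigs = normalized_laplacian_spectrum(g)
        assert eigs[0] == pytest.approx(0.0, abs=1e-9)
        assert eigs[-1] <= 2.0 + 1e-9
        assert eigs.sum() == pytest.approx(10.0, abs=1e-8)
        # for k-regular graphs L = I - A/k elementwise in the spectrum
        mu = np.sort(np.linalg.eigvalsh(nx.to_numpy_array(g)))[::-1]
        assert np.allclose(eigs, 1.0 - mu / 3.0, atol=1e-9)

    def test_isolated_vertex_rejected(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        with pytest.raises(ValueError, match="isolated"):
            normalized_laplacian_spectrum(g)


class TestDensity:
    def test_single_eigenvalue_is_unit_mass_gaussian(self):
        grid = np.linspace(-3, 5, 4001)
        dens = smoothed_density(np.array([1.0]), sigma=0.1, grid=grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-8)
        assert grid[np.argmax(dens)] == pytest.approx(1.0, abs=1e-3)

    def test_k4_density_mass_is_n(self):
        eigs = normalized_laplacian_spectrum(complete_graph(4))
        grid = np.linspace(-1, 3, 8001)
        dens = smoothed_density(eigs, sigma=1 / 12, grid=grid)
        assert np.trapezoid(dens, grid) == pytest.approx(4.0, abs=1e-6)

    def test_identical_spectra_identical_densities(self):
        e = normalized_laplacian_spectrum(cycle_graph(6))
        assert np.array_equal(smoothed_density(e), smoothed_density(e.copy()))


class TestDistance:
    def test_pseudometric_axioms(self):
        k4 = SpectralSummary.from_graph(complete_graph(4))
        c4 = SpectralSummary.from_graph(cycle_graph(4))
        assert spectral_distance(k4, k4) == 0.0
        d1, d2 = spectral_distance(k4, c4), spectral_distance(c4, k4)
        assert d1 == pytest.approx(d2)
        assert d1 > 0.0

    def test_triangle_inequality_on_cubic10_triple(self):
        graphs = list(enumerate_regular(10, 3))[:3]
        a, b, c = (SpectralSummary.from_graph(g) for g in graphs)
        assert spectral_distance(a, c) <= (
            spectral_distance(a, b) + spectral_distance(b, c) + 1e-12
        )

    def test_mismatched_grids_rejected(self):
        a = SpectralSummary.from_graph(complete_graph(4), grid=default_grid(101))
        b = SpectralSummary.from_graph(complete_graph(4), grid=default_grid(201))
        with pytest.raises(ValueError, match="grid"):
            spectral_distance(a, b)


class TestEntropy:
    def test_k2_entropy_is_zero(self):
        assert von_neumann_entropy(np.array([0.0, 2.0])) == pytest.approx(0.0)

    @pytest.mark.parametrize("N", [4, 6, 10])
    def test_complete_graph_entropy(self, N):
        eigs = normalized_laplacian_spectrum(complete_graph(N))
        assert von_neumann_entropy(eigs) == pytest.approx(np.log2(N - 1), abs=1e-9)

    @pytest.mark.parametrize("N", [4, 6, 10])
    def test_complete_graph_maximizes_entropy_over_cycle(self, N):
        # K_N has the flattest nonzero spectrum (N-1 equal eigenvalues), so its
        # entropy log2(N-1) exceeds the cycle's at equal order
        s_cycle = von_neumann_entropy(normalized_laplacian_spectrum(cycle_graph(N)))
        s_complete = von_neumann_entropy(normalized_laplacian_spectrum(complete_graph(N)))
        assert s_cycle < s_complete

    def test_entropy_bounds(self):
        for g in (nx.petersen_graph(), cycle_graph(9)):
            s = von_neumann_entropy(normalized_laplacian_spectrum(g))
            assert 0.0 <= s <= np.log2(g.number_of_nodes())


class TestKestenMcKay:
    def test_support_endpoints_vanish(self):
        for k in (3, 4):
            half = 2 * np.sqrt(k - 1) / k
            # the numerator vanishes at the edge; float rounding of the
            # endpoint leaves at most an O(sqrt(eps)) residue
            assert kesten_mckay_density(1 - half, k) == pytest.approx(0.0, abs=1e-6)
            assert kesten_mckay_density(1 + half, k) == pytest.approx(0.0, abs=1e-6)
            assert kesten_mckay_density(1 - half - 0.05, k) == 0.0

    def test_center_value_cubic(self):
        # the common unnormalized form evaluates to sqrt(2)/(3 pi) at x = 1
        assert kesten_mckay_density(1.0, 3, normalized=False) == pytest.approx(
            np.sqrt(2) / (3 * np.pi)
        )
        assert kesten_mckay_density(1.0, 3) == pytest.approx(np.sqrt(2) / np.pi)

    @pytest.mark.parametrize("k", [3, 4])
    def test_density_integrates_to_one(self, k):
        half = 2 * np.sqrt(k - 1) / k
        total, _ = quad(lambda x: kesten_mckay_density(x, k), 1 - half, 1 + half)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_low_degree_rejected(self):
        with pytest.raises(ValueError):
            kesten_mckay_density(1.0, 2)


class TestRemeetingBound:
    @pytest.mark.parametrize("N", [4, 7, 11])
    def test_equality_on_complete_graph(self, N):
        holds, slack = remeeting_bound(complete_graph(N))
        assert holds
        assert slack == pytest.approx(0.0, abs=1e-8)

    def test_strict_slack_on_cycle(self):
        holds, slack = remeeting_bound(cycle_graph(8))
        assert holds
        assert slack > 0.1

    def test_zero_gap_rejected(self):
        summary = coalescence_times(cycle_graph(6))
        with pytest.raises(ValueError, match="spectral gap"):
            remeeting_bound(cycle_graph(6), coalescence=summary, spectrum=np.zeros(6))


def test_family_density_is_mean_of_members():
    fam = FamilySpectral.from_graphs([complete_graph(4), cycle_graph(4)])
    manual = fam.member_densities.mean(axis=0)
    assert np.array_equal(fam.family_density, manual)
    assert fam.distance(fam) == 0.0
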