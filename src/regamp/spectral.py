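"""Normalized-Laplacian spectral characterization of regular graphs.

The spectrum of ``L = I - D^{-1/2} A D^{-1/2}`` lives in [0, 2] for every
graph, which makes it convenient for comparing graphs across orders and
degrees.  The module computes the spectrum and spectral gap, a smoothed
spectral density (eigenvalues convolved with a Gaussian kernel of width
``sigma = 1/(3N)``), an L1 pseudometric between densities, the von Neumann
graph entropy, the Kesten-McKay reference density of large random k-regular
graphs, and the spectral-gap bound on remeeting times

    tau_i <= (N - 1)/lambda_2 + (2N - 1)/N,

which is tight on the complete graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg

__all__ = [
    "SpectralSummary",
    "FamilySpectral",
    "default_grid",
    "normalized_laplacian_spectrum",
    "smoothed_density",
    "spectral_distance",
    "von_neumann_entropy",
    "kesten_mckay_density",
    "remeeting_bound",
]

GRID_POINTS = 2001
_CLIP_TOL = 1e-9


def default_grid(n_points: int = GRID_POINTS) -> np.ndarray:
    """Equidistant evaluation grid on [0, 2] shared by all densities."""
    return np.linspace(0.0, 2.0, n_points)


def normalized_laplacian_spectrum(g: nx.Graph) -> np.ndarray:
    """Ascending eigenvalues of the normalized Laplacian, clipped to [0, 2]."""
    if any(d == 0 for _, d in g.degree()):
        raise ValueError("normalized Laplacian undefined for isolated vertices")
    nodes = sorted(g.nodes())
    L = nx.normalized_laplacian_matrix(g, nodelist=nodes).toarray()
    eigs = scipy.linalg.eigvalsh(L)
    if eigs[0] < -_CLIP_TOL or eigs[-1] > 2.0 + _CLIP_TOL:
        raise RuntimeError("normalized-Laplacian eigenvalue outside [0, 2]")
    return np.clip(np.sort(eigs), 0.0, 2.0)


def smoothed_density(
    eigenvalues: np.ndarray, sigma: float | None = None, grid: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian-kernel density of the spectrum on the common grid.

    Each eigenvalue contributes a unit-mass Gaussian of width ``sigma``
    (default 1/(3N)), so the density integrates to N over the real line.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if sigma is None:
        sigma = 1.0 / (3.0 * eigenvalues.size)
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    if grid is None:
        grid = default_grid()
    z = (grid[:, None] - eigenvalues[None, :]) / sigma
    return np.exp(-0.5 * z**2).sum(axis=1) / np.sqrt(2.0 * np.pi * sigma**2)


@dataclass
class SpectralSummary:
    """Spectrum and derived quantities of a single graph."""

    eigenvalues: np.ndarray
    sigma: float
    grid: np.ndarray
    density: np.ndarray
    entropy: float

    @property
    def order(self) -> int:
        return self.eigenvalues.size

    @property
    def spectral_gap(self) -> float:
        return float(self.eigenvalues[1])

    @classmethod
    def from_graph(cls, g: nx.Graph, grid: np.ndarray | None = None) -> "SpectralSummary":
        eigs = normalized_laplacian_spectrum(g)
        sigma = 1.0 / (3.0 * eigs.size)
        if grid is None:
            grid = default_grid()
        return cls(
            eigenvalues=eigs,
            sigma=sigma,
            grid=grid,
            density=smoothed_density(eigs, sigma, grid),
            entropy=von_neumann_entropy(eigs),
        )


def spectral_distance(a, b) -> float:
    """L1 distance between two smoothed spectral densities over [0, 2].

    Accepts :class:`SpectralSummary` objects or raw density arrays on the
    default grid; the grids must coincide.
    """
    grid_a, dens_a = _grid_density(a)
    grid_b, dens_b = _grid_density(b)
    if grid_a.shape != grid_b.shape or not np.allclose(grid_a, grid_b):
        raise ValueError("spectral distance requires a common evaluation grid")
    return float(np.trapezoid(np.abs(dens_a - dens_b), grid_a))


def _grid_density(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, SpectralSummary):
        return obj.grid, obj.density
    if isinstance(obj, FamilySpectral):
        return obj.grid, obj.family_density
    return default_grid(len(obj)), np.asarray(obj, dtype=float)


def von_neumann_entropy(eigenvalues: np.ndarray, order: int | None = None) -> float:
    """Shannon entropy (bits) of the eigenvalues normalized by 1/N.

    The normalized values nu_i = lambda_i / N sum to one because the trace of
    the normalized Laplacian equals N; zero eigenvalues contribute nothing.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if order is None:
        order = eigenvalues.size
    nu = eigenvalues / order
    nz = nu[nu > 0]
    return float(-(nz * np.log2(nz)).sum())


def kesten_mckay_density(x, k: int, normalized: bool = True):
    """Limiting spectral density of random k-regular graphs (normalized Laplacian).

    Supported on ``|1 - x| <= 2 sqrt(k-1)/k`` and zero outside.  With
    ``normalized=True`` (default) the density integrates to one; the commonly
    printed form sqrt(4(k-1) - k^2 (1-x)^2) / (2 pi k (2-x) x), obtained by
    ``normalized=False``, carries total mass 1/k because the substitution
    x = 1 - mu/k from the adjacency spectrum contributes a Jacobian factor k.
    """
    if k < 3:
        raise ValueError("Kesten-McKay density needs degree k >= 3")
    x = np.asarray(x, dtype=float)
    halfwidth = 2.0 * np.sqrt(k - 1.0) / k
    inside = np.abs(1.0 - x) <= halfwidth
    out = np.zeros_like(x)
    xv = x[inside]
    num = np.sqrt(np.maximum(4.0 * (k - 1.0) - k**2 * (1.0 - xv) ** 2, 0.0))
    scale = 1.0 if normalized else float(k)
    out[inside] = num / (2.0 * np.pi * scale * (2.0 - xv) * xv)
    return out if out.ndim else float(out)


def remeeting_bound(g: nx.Graph, coalescence=None, spectrum=None) -> tuple[bool, float]:
    """Check tau_i <= (N-1)/lambda_2 + (2N-1)/N for every vertex.

    Returns ``(holds, min_slack)`` where the slack is the bound minus the
    largest remeeting time; equality (zero slack) holds on complete graphs.
    """
    from .coalescence import coalescence_times

    if coalescence is None:
        coalescence = coalescence_times(g)
    if spectrum is None:
        spectrum = normalized_laplacian_spectrum(g)
    lam2 = float(spectrum[1])
    if lam2 <= _CLIP_TOL:
        raise ValueError("zero spectral gap (disconnected graph): bound undefined")
    n = g.number_of_nodes()
    bound = (n - 1) / lam2 + (2 * n - 1) / n
    slack = float(bound - coalescence.tau_remeet.max())
    return slack >= -1e-8, slack


# ---------------------------------------------------------------------------
# graph families
# ---------------------------------------------------------------------------

@dataclass
class FamilySpectral:
    """Mean smoothed spectral density of a family of graphs on a common grid."""

    grid: np.ndarray
    member_densities: np.ndarray  # (n_members, n_grid)

    @classmethod
    def from_graphs(cls, graphs, grid: np.ndarray | None = None) -> "FamilySpectral":
        if grid is None:
            grid = default_grid()
        dens = [SpectralSummary.from_graph(g, grid).density for g in graphs]
        if not dens:
            raise ValueError("family must contain at least one graph")
        return cls(grid=grid, member_densities=np.array(dens))

    @classmethod
    def from_spectra(cls, spectra, grid: np.ndarray | None = None) -> "FamilySpectral":
        if grid is None:
            grid = default_grid()
        dens = [smoothed_density(e, None, grid) for e in spectra]
        if not dens:
            raise ValueError("family must contain at least one spectrum")
        return cls(grid=grid, member_densities=np.array(dens))

    @property
    def family_density(self) -> np.ndarray:
        return self.member_densities.mean(axis=0)

    def distance(self, other) -> float:
        return spectral_distance(self, other)
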