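"""Conditional free-energy landscapes over (Rg, RMSD) coordinates.

The landscape is obtained from a 2D Gaussian-kernel probability density
P(r) of the structural coordinates and the Boltzmann inversion

    E(r) = -R*T * ln( P(r) / P_max ),

so the global density maximum sits at E = 0 and every other cell carries a
non-negative conditional free energy (kJ/mol).  Cells with zero density are
formally at +infinity; writers cap them at a configurable value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GAS_CONSTANT_KJ", "Landscape2D", "density_2d",
           "conditional_energy", "free_energy_landscape"]

#: ideal gas constant, kJ/(mol K)
GAS_CONSTANT_KJ = 8.314e-3

#: default grid-cell area (Angstrom^2); square cells of side sqrt(0.009)
DEFAULT_CELL_AREA = 0.009


@dataclass
class Landscape2D:
    """Gridded density/energy surface over two structural coordinates."""

    x: np.ndarray  # grid along the first coordinate (e.g. Rg, Angstrom)
    y: np.ndarray  # grid along the second coordinate (e.g. RMSD, Angstrom)
    density: np.ndarray  # (nx, ny), normalized over the grid
    energy: np.ndarray | None = None  # (nx, ny), kJ/mol; inf where P = 0
    temperature: float | None = None  # K
    bandwidth: tuple[float, float] | None = None
    grid_step: tuple[float, float] | None = None

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.y, axis=1),
                                  self.x))

    @property
    def peak(self) -> tuple[float, float]:
        """(x, y) location of the density maximum."""
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.x[i]), float(self.y[j])


def _silverman_bandwidth(data: np.ndarray) -> float:
    # d = 2 Gaussian reference rule: h = sigma * n^(-1/(d+4))
    n = len(data)
    return float(np.std(data, ddof=1) * n ** (-1.0 / 6.0))


def density_2d(points, bandwidth="auto", grid_step=None) -> Landscape2D:
    """Gaussian-kernel density of 2D structural coordinates on a regular grid.

    Parameters
    ----------
    points:
        ``(n, 2)`` array of (Rg, RMSD) pairs, n >= 10.
    bandwidth:
        Per-axis kernel widths ``(hx, hy)``, a scalar used for both axes, or
        ``"auto"`` for Silverman's rule per axis.
    grid_step:
        Per-axis grid spacing; default square cells of side
        ``sqrt(0.009) ~ 0.095`` Angstrom.  The grid covers the data range
        plus three bandwidths on each side and the density is renormalized
        to integrate to 1 over it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(pts) < 10:
        raise ValueError(f"need >=10 points for a density estimate, got {len(pts)}")
    if np.ptp(pts, axis=0).max() == 0.0:
        raise ValueError("all points identical: zero-variance density")

    if isinstance(bandwidth, str):
        if bandwidth != "auto":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        bw = (_silverman_bandwidth(pts[:, 0]), _silverman_bandwidth(pts[:, 1]))
    else:
        bw = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,))
        bw = (float(bw[0]), float(bw[1]))
    if not all(np.isfinite(b) and b > 0 for b in bw):
        raise ValueError(f"bandwidths must be finite and positive, got {bw}")

    if grid_step is None:
        step = np.sqrt(DEFAULT_CELL_AREA)
        grid_step = (step, step)
    else:
        gs = np.broadcast_to(np.asarray(grid_step, dtype=float), (2,))
        grid_step = (float(gs[0]), float(gs[1]))

    axes = []
    for k in range(2):
        lo = pts[:, k].min() - 3.0 * bw[k]
        hi = pts[:, k].max() + 3.0 * bw[k]
        n_cells = max(int(np.ceil((hi - lo) / grid_step[k])), 2)
        axes.append(lo + grid_step[k] * np.arange(n_cells + 1))
    gx, gy = axes

    # separable product kernel: D = A @ B / (2 pi n hx hy)
    ax = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / bw[0]) ** 2)
    by = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / bw[1]) ** 2)
    dens = ax @ by.T / (2.0 * np.pi * len(pts) * bw[0] * bw[1])

    ls = Landscape2D(x=gx, y=gy, density=dens, bandwidth=bw,
                     grid_step=grid_step)
    ls.density = dens / ls.integral()
    return ls


def conditional_energy(landscape: Landscape2D, temperature: float = 310.0) -> Landscape2D:
    """Fill the energy surface E = -RT ln(P/Pmax) of a computed density.

    The minimum is exactly 0 at the density maximum; zero-density cells get
    ``+inf``.  Temperature in kelvin (default 310 K).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    p = landscape.density
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("density is identically zero")
    with np.errstate(divide="ignore"):
        energy = -GAS_CONSTANT_KJ * temperature * np.log(p / pmax)
    return replace(landscape, energy=energy, temperature=temperature)


def free_energy_landscape(points, temperature: float = 310.0,
                          bandwidth="auto", grid_step=None) -> Landscape2D:
    """Density estimation and Boltzmann inversion in one call."""
    return conditional_energy(density_2d(points, bandwidth, grid_step),
                              temperature)
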