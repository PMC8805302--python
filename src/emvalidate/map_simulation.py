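"""Theoretical density from an atomic model, via a Gaussian-atom approximation.

Each non-hydrogen atom contributes an isotropic 3-D Gaussian whose real-space
variance follows from its displacement parameter, sigma^2 = B/(8 pi^2), and
whose integrated density is proportional to occupancy times atomic number.
A resolution-dependent blur B is added to every atom so that maps remain
meaningful for unrefined (B = 0) models, and the summed map is band-limited
with a raised-cosine low-pass at the requested resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .volumetric_io import DensityGrid

logger = logging.getLogger(__name__)

__all__ = ["SimulationParams", "simulate_map", "lowpass_filter", "default_blur_b"]

_EIGHT_PI_SQ = 8.0 * math.pi**2


def default_blur_b(resolution: float) -> float:
    """Blur B (Å²) at which an atom's Fourier amplitude exp(-B s²/4) falls to
    one half at the resolution cutoff s = 1/resolution."""
    return 4.0 * math.log(2.0) * resolution**2


@dataclass
class SimulationParams:
    """Settings for computing a theoretical map.

    Parameters
    ----------
    resolution : float
        Target resolution (Å); the simulated map is low-pass filtered here.
    grid_template : DensityGrid
        Defines the sampling geometry (shape, voxel size, origin) of the output.
    use_b_factors : bool
        Whether per-atom B factors broaden the atom Gaussians.
    global_blur_b : float or None
        Extra B (Å²) added to every atom; ``None`` selects the resolution-matched
        default from :func:`default_blur_b`.
    """

    resolution: float
    grid_template: DensityGrid
    use_b_factors: bool = True
    global_blur_b: float | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.global_blur_b is None:
            self.global_blur_b = default_blur_b(self.resolution)


def _atomic_number(element: str) -> int:
    z = gemmi.Element(element).atomic_number
    if z == 0:
        logger.warning("unknown element %r; treating as carbon", element)
        z = 6
    return z


def simulate_map(model, params: SimulationParams, lowpass: bool = True) -> DensityGrid:
    """Sum Gaussian atom densities on the template grid.

    Each atom's Gaussian is normalized (integral = occupancy x Z), truncated at
    4 sigma, and sampled at voxel centers.  Hydrogens and zero-occupancy atoms
    are skipped.  When ``lowpass`` is set the summed map is band-limited at
    ``params.resolution`` if the grid sampling allows it.
    """
    tmpl = params.grid_template
    shape = tmpl.shape
    vox = np.asarray(tmpl.voxel_size)
    out = np.zeros(shape, dtype=np.float64)

    n_inside = 0
    for key, atom in model.atoms():
        if atom.element.upper() in ("H", "D"):
            continue
        if atom.occupancy <= 0.0:
            continue
        b_total = (atom.b_factor if params.use_b_factors else 0.0) + params.global_blur_b
        sigma = math.sqrt(max(b_total, 1e-6) / _EIGHT_PI_SQ)
        center = tmpl.coord_to_index(atom.coord)  # fractional voxel index
        radius_vox = 4.0 * sigma / vox
        lo = np.maximum(np.ceil(center - radius_vox).astype(int), 0)
        hi = np.minimum(np.floor(center + radius_vox).astype(int), np.array(shape) - 1)
        if np.any(lo > hi):
            continue
        n_inside += 1
        ix = np.arange(lo[0], hi[0] + 1)
        iy = np.arange(lo[1], hi[1] + 1)
        iz = np.arange(lo[2], hi[2] + 1)
        dx2 = ((ix - center[0]) * vox[0]) ** 2
        dy2 = ((iy - center[1]) * vox[1]) ** 2
        dz2 = ((iz - center[2]) * vox[2]) ** 2
        r2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        amp = atom.occupancy * _atomic_number(atom.element) / (
            (2.0 * math.pi * sigma**2) ** 1.5
        )
        g = amp * np.exp(-r2 / (2.0 * sigma**2))
        g[r2 > (4.0 * sigma) ** 2] = 0.0
        out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += g

    if n_inside == 0:
        raise ValueError("model lies entirely outside the grid")

    grid = tmpl.with_values(out)
    if lowpass and params.resolution >= 2.0 * max(tmpl.voxel_size):
        grid = lowpass_filter(grid, params.resolution)
    return grid


def lowpass_filter(grid: DensityGrid, resolution: float) -> DensityGrid:
    """Band-limit a grid at 1/resolution with a raised-cosine edge.

    The edge spans two Fourier shells beyond the cutoff; the DC term is
    untouched so the mean value is preserved.
    """
    if resolution < 2.0 * max(grid.voxel_size):
        raise ValueError(
            f"resolution {resolution} Å is below Nyquist for voxel size {grid.voxel_size}"
        )
    nx, ny, nz = grid.shape
    vx, vy, vz = grid.voxel_size
    fx = np.fft.fftfreq(nx, d=vx)
    fy = np.fft.fftfreq(ny, d=vy)
    fz = np.fft.rfftfreq(nz, d=vz)
    s = np.sqrt(
        fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    )
    # one Fourier shell = coarsest frequency step of the box
    ds = max(1.0 / (nx * vx), 1.0 / (ny * vy), 1.0 / (nz * vz))
    s_cut = 1.0 / resolution
    edge = 2.0 * ds
    w = np.ones_like(s)
    in_edge = (s > s_cut) & (s < s_cut + edge)
    w[in_edge] = 0.5 * (1.0 + np.cos(math.pi * (s[in_edge] - s_cut) / edge))
    w[s >= s_cut + edge] = 0.0
    F = np.fft.rfftn(grid.values)
    filtered = np.fft.irfftn(F * w, s=grid.shape, axes=(0, 1, 2))
    return grid.with_values(filtered)
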