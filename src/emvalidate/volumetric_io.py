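"""Reading, writing and characterizing cryo-EM density volumes.

Volumes are held in a :class:`DensityGrid`: a float array indexed
``[ix, iy, iz]`` (x fastest-moving physical axis first) together with the
physical voxel spacing and the absolute position of voxel ``(0, 0, 0)``.
All downstream scoring code assumes this normalized layout; arbitrary axis
orders found in MRC/CCP4 files are permuted to x,y,z on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "ContourLevel",
    "ContourSource",
    "MapFormatError",
    "DegenerateMapError",
    "read_map",
    "write_map",
    "estimate_contour",
    "masked_fraction",
]


class MapFormatError(ValueError):
    """The file is not a readable MRC/CCP4 volume."""


class DegenerateMapError(ValueError):
    """The map content does not support the requested computation."""


@dataclass(frozen=True)
class DensityGrid:
    """A 3-D density volume with physical metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density values; the first index runs along physical x.
    voxel_size : tuple of float
        Spacing (Å) along x, y, z.
    origin : tuple of float
        Position (Å) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or min(v.shape) < 2:
            raise ValueError(f"grid must be 3-D with all dims >= 2, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("grid values must be finite")
        vs = tuple(float(x) for x in self.voxel_size)
        if len(vs) != 3 or min(vs) <= 0:
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def coord_to_index(self, coord: np.ndarray) -> np.ndarray:
        """Map Cartesian coordinates (Å) to fractional voxel indices (0-based)."""
        coord = np.asarray(coord, dtype=float)
        return (coord - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def index_to_coord(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.voxel_size)

    def same_geometry(self, other: "DensityGrid", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "DensityGrid":
        return DensityGrid(values, self.voxel_size, self.origin)


class ContourSource(str, Enum):
    USER = "user"
    AUTO_SIGMA = "auto_sigma"


@dataclass(frozen=True)
class ContourLevel:
    """A density threshold delimiting the molecular volume."""

    level: float
    source: ContourSource = ContourSource.USER

    def __post_init__(self) -> None:
        if not np.isfinite(self.level):
            raise ValueError("contour level must be finite")


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 volume, normalizing axis order to x,y,z.

    The origin is taken from the MRC2014 ORIGIN header words when any is
    nonzero, otherwise reconstructed as ``start * voxel_size`` from the
    NC/NR/NS start fields.
    """
    path = Path(path)
    if not path.is_file():
        raise MapFormatError(f"no such map file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read {path} as MRC/CCP4: {exc}") from exc

    # raw header fields, in file (column/row/section) order
    starts_crs = [m.header_i32(i) for i in (5, 6, 7)]
    axis_map = [m.header_i32(i) for i in (17, 18, 19)]  # MAPC, MAPR, MAPS
    if sorted(axis_map) != [1, 2, 3]:
        raise MapFormatError(f"invalid axis order words {axis_map} in {path}")
    origin_words = [m.header_float(i) for i in (50, 51, 52)]

    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True, dtype=np.float64)
    if values.ndim != 3:
        raise MapFormatError(f"{path} does not hold a 3-D volume")
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"{path} contains non-finite or missing voxels")

    cell = m.grid.unit_cell
    nu, nv, nw = values.shape
    voxel = (cell.a / nu, cell.b / nv, cell.c / nw)
    if min(voxel) <= 0:
        raise MapFormatError(f"{path} has a zero voxel size")

    if any(abs(w) > 1e-6 for w in origin_words):
        origin = tuple(float(w) for w in origin_words)
    else:
        start_xyz = [0, 0, 0]
        for file_axis, xyz_axis in enumerate(axis_map):
            start_xyz[xyz_axis - 1] = starts_crs[file_axis]
        origin = tuple(start_xyz[k] * voxel[k] for k in range(3))

    return DensityGrid(values, voxel, origin)


def write_map(grid: DensityGrid, path) -> None:
    """Write a grid as an MRC2014 mode-2 (float32) volume."""
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.shape
    vx, vy, vz = grid.voxel_size
    g.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(value))
    m.write_ccp4_map(str(path))


def estimate_contour(grid: DensityGrid, n_sigma: float = 1.5, bins: int = 128) -> ContourLevel:
    """Automatic contour level at ``n_sigma`` background spreads above the background peak.

    The background peak is the center of the modal bin of a histogram over the
    full value range.  The spread is estimated from the voxels at or below the
    peak only, mirrored about it, so the signal tail above the peak does not
    inflate it.
    """
    v = grid.values.ravel()
    if v.max() == v.min():
        raise DegenerateMapError("constant map has no contour")
    counts, edges = np.histogram(v, bins=bins)
    k = int(np.argmax(counts))
    mode = 0.5 * (edges[k] + edges[k + 1])
    below = v[v <= mode] - mode
    if below.size == 0:
        raise DegenerateMapError("no voxels at or below the background peak")
    spread = float(np.sqrt(np.mean(below**2)))
    if spread == 0.0:
        raise DegenerateMapError("zero background spread")
    return ContourLevel(level=mode + n_sigma * spread, source=ContourSource.AUTO_SIGMA)


def masked_fraction(grid: DensityGrid) -> float:
    """Fraction of voxels exactly equal to zero (a masking fingerprint)."""
    return float(np.mean(grid.values == 0.0))
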