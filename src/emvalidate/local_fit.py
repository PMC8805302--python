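"""Per-residue local fit: segment-based Manders' overlap (SMOC) and
neighborhood Z-score outlier detection.

Each residue is scored over its own voxel footprint — the union of voxels
within a fixed radius of any of its atoms — by the Manders' overlap
coefficient between the simulated and the experimental density restricted to
that footprint.  Because local density levels vary across a map, raw SMOC
values are converted to Z-scores against the residues within a 12 Å
neighborhood; residues with Z below -1.5 are flagged as potential misfits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .map_simulation import SimulationParams, simulate_map
from .model_io import AtomicModel, ResidueKey, ca_coordinates
from .volumetric_io import DensityGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueScoreSeries",
    "SmocParams",
    "residue_footprint",
    "manders_overlap",
    "smoc",
    "local_zscores",
]


@dataclass
class ResidueScoreSeries:
    """Ordered per-residue values of one metric plus outlier flags."""

    metric_name: str
    values: dict[ResidueKey, float]
    outlier_flags: dict[ResidueKey, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.values:
            self.outlier_flags.setdefault(key, False)

    def outliers(self) -> list[ResidueKey]:
        return [k for k, flagged in self.outlier_flags.items() if flagged]


@dataclass
class SmocParams:
    footprint_radius: float | None = None  # None -> max(2.5 Å, 1.5 x voxel)
    neighborhood_radius: float = 12.0
    z_cutoff: float = -1.5

    def resolved_radius(self, grid: DensityGrid) -> float:
        if self.footprint_radius is not None:
            if self.footprint_radius <= 0:
                raise ValueError("footprint radius must be positive")
            return self.footprint_radius
        return max(2.5, 1.5 * max(grid.voxel_size))


def residue_footprint(
    model: AtomicModel, residue: ResidueKey, grid: DensityGrid, radius: float
) -> np.ndarray:
    """Sorted flat voxel indices within ``radius`` of any atom of the residue.

    Atoms outside the grid contribute nothing; a residue entirely outside
    yields an empty footprint (logged).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    shape = np.array(grid.shape)
    vox = np.asarray(grid.voxel_size)
    hits: set[int] = set()
    for atom in model.residues[residue]:
        center = grid.coord_to_index(atom.coord)
        lo = np.maximum(np.ceil(center - radius / vox).astype(int), 0)
        hi = np.minimum(np.floor(center + radius / vox).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        ix = np.arange(lo[0], hi[0] + 1)
        iy = np.arange(lo[1], hi[1] + 1)
        iz = np.arange(lo[2], hi[2] + 1)
        r2 = (
            (((ix - center[0]) * vox[0]) ** 2)[:, None, None]
            + (((iy - center[1]) * vox[1]) ** 2)[None, :, None]
            + (((iz - center[2]) * vox[2]) ** 2)[None, None, :]
        )
        sel = np.argwhere(r2 <= radius**2)
        if sel.size:
            flat = np.ravel_multi_index(
                (sel[:, 0] + lo[0], sel[:, 1] + lo[1], sel[:, 2] + lo[2]), grid.shape
            )
            hits.update(flat.tolist())
    if not hits:
        logger.warning("residue %s has an empty footprint (outside grid?)", residue.label())
        return np.empty(0, dtype=np.intp)
    return np.array(sorted(hits), dtype=np.intp)


def manders_overlap(sim: np.ndarray, exp: np.ndarray) -> float:
    """Manders' overlap coefficient sum(s*e)/sqrt(sum(s^2) sum(e^2)) for two
    value vectors; 0 when either vector is identically zero."""
    s = np.asarray(sim, dtype=float)
    e = np.asarray(exp, dtype=float)
    den = np.sqrt(np.sum(s**2) * np.sum(e**2))
    if den == 0:
        return 0.0
    return float(np.clip(np.sum(s * e) / den, -1.0, 1.0))


def smoc(
    model: AtomicModel,
    exp_map: DensityGrid,
    params: SimulationParams,
    smoc_params: SmocParams | None = None,
) -> ResidueScoreSeries:
    """Per-residue SMOC of a model against an experimental map.

    The theoretical map is simulated on the experimental grid; experimental
    values are clamped below at zero so the score stays within [0, 1].
    Residues with a degenerate (empty or zero-density) footprint are omitted.
    """
    smoc_params = smoc_params or SmocParams()
    radius = smoc_params.resolved_radius(exp_map)
    sim = simulate_map(model, replace(params, grid_template=exp_map))
    s_flat = np.clip(sim.values.ravel(), 0.0, None)
    e_flat = np.clip(exp_map.values.ravel(), 0.0, None)

    values: dict[ResidueKey, float] = {}
    for key in model.residues:
        fp = residue_footprint(model, key, exp_map, radius)
        if fp.size == 0:
            logger.warning("residue %s unscored: empty footprint", key.label())
            continue
        moc = manders_overlap(s_flat[fp], e_flat[fp])
        if np.sum(s_flat[fp] ** 2) == 0:
            logger.warning("residue %s unscored: no simulated density", key.label())
            continue
        values[key] = float(np.clip(moc, 0.0, 1.0))
    return ResidueScoreSeries(metric_name="smoc", values=values)


def local_zscores(
    series: ResidueScoreSeries,
    model: AtomicModel,
    smoc_params: SmocParams | None = None,
) -> ResidueScoreSeries:
    """Z-score of each residue's score against its spatial neighborhood.

    The neighborhood of residue r is every scored residue whose CA (P for
    nucleotides) lies within ``neighborhood_radius`` of r's CA, r included.
    Degenerate neighborhoods (size 1 or zero spread) give Z = 0.
    """
    smoc_params = smoc_params or SmocParams()
    coords_map = ca_coordinates(model)
    keys = [k for k in series.values if k in coords_map]
    if not keys:
        raise ValueError("no scored residue has a CA/P reference coordinate")
    coords = np.array([coords_map[k] for k in keys])
    scores = np.array([series.values[k] for k in keys])

    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r=smoc_params.neighborhood_radius)
    z_values: dict[ResidueKey, float] = {}
    flags: dict[ResidueKey, bool] = {}
    for i, key in enumerate(keys):
        nb = scores[neighbor_lists[i]]
        if nb.size <= 1:
            logger.info("residue %s: neighborhood of size 1; Z set to 0", key.label())
            z = 0.0
        else:
            sd = nb.std()
            if sd <= 1e-12 * max(1.0, float(np.abs(nb).max())):  # constant up to roundoff
                z = 0.0
            else:
                z = float((scores[i] - nb.mean()) / sd)
        z_values[key] = z
        flags[key] = z < smoc_params.z_cutoff
    return ResidueScoreSeries(metric_name="smoc_z", values=z_values, outlier_flags=flags)
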