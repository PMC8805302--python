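"""Backbone validation through false-discovery-rate confidence maps.

Background noise statistics are estimated from windows at the volume
periphery (assuming a centered particle and an unmasked map), per-voxel
right-tail p-values are computed under that Gaussian noise model, and a
Benjamini–Yekutieli adjustment controls the FDR across all voxels.  The
resulting per-voxel confidence (1 - adjusted q) separates molecular signal
from background; running the procedure over a small scan of resolutions and
pooling by voxel-wise maximum makes the segmentation robust to local blur.

The per-residue backbone score is the fraction of a residue's backbone atoms
sitting in confident volume; residues scoring below 0.9 are flagged, and the
fraction of residues scoring above 0.9 summarizes the whole model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .map_simulation import lowpass_filter
from .model_io import AtomicModel, ResidueKey, backbone_atoms
from .volumetric_io import DensityGrid, masked_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceGrid",
    "BackboneScoreParams",
    "MaskedMapError",
    "estimate_noise",
    "confidence_map",
    "fdr_backbone_scores",
    "overall_fdr_metric",
]

MASKED_FRACTION_LIMIT = 0.05


class MaskedMapError(ValueError):
    """The map appears masked; an unmasked map is required for FDR scoring."""


@dataclass
class ConfidenceGrid:
    """Per-voxel confidence (1 - adjusted q) with source metadata."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    source_resolutions: list[float]
    noise_mean: float
    noise_sd: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("confidence values must lie in [0, 1]")
        self.values = v

    def coord_to_index(self, coord) -> np.ndarray:
        coord = np.asarray(coord, dtype=float)
        return (coord - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def to_density_grid(self) -> DensityGrid:
        """View as a plain grid, e.g. for writing to MRC for visual inspection."""
        return DensityGrid(self.values, self.voxel_size, self.origin)


@dataclass
class BackboneScoreParams:
    residue_cutoff: float = 0.9
    q: float = 0.01
    resolutions_scan: list[float] | None = None  # None -> {R, 1.5R, 2R} at runtime

    def __post_init__(self) -> None:
        if not 0.0 < self.residue_cutoff < 1.0:
            raise ValueError("residue cutoff must lie in (0, 1)")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")

    def scan_for(self, nominal_resolution: float) -> list[float]:
        if self.resolutions_scan:
            return list(self.resolutions_scan)
        return [nominal_resolution, 1.5 * nominal_resolution, 2.0 * nominal_resolution]


def _periphery_windows(shape: tuple[int, int, int]) -> list[tuple[slice, slice, slice]]:
    """Twelve background windows: the 8 corner cubes plus 4 z-centered edge
    windows, each with edge length dim/8 (minimum 2 voxels)."""
    edges = [max(2, n // 8) for n in shape]
    lo = [slice(0, e) for e in edges]
    hi = [slice(n - e, n) for n, e in zip(shape, edges)]
    windows = [(a, b, c) for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])]
    zc = shape[2] // 2
    mid = slice(max(0, zc - edges[2] // 2), min(shape[2], zc + max(1, edges[2] // 2)))
    windows += [(a, b, mid) for a in (lo[0], hi[0]) for b in (lo[1], hi[1])]
    return windows


def estimate_noise(grid: DensityGrid) -> tuple[float, float]:
    """Gaussian background parameters from periphery windows of an unmasked map.

    Raises :class:`MaskedMapError` when a meaningful fraction of voxels is
    exactly zero (the fingerprint of a multiplied-in mask).  Warns when the
    per-window spreads are too heterogeneous for a common noise model.
    """
    mf = masked_fraction(grid)
    if mf >= MASKED_FRACTION_LIMIT:
        raise MaskedMapError(
            f"{mf:.0%} of voxels are exactly zero; an unmasked map is required "
            "for background-noise estimation"
        )
    windows = _periphery_windows(grid.shape)
    samples = [grid.values[w].ravel() for w in windows]
    sds = np.array([s.std() for s in samples])
    positive = sds[sds > 0]
    if positive.size and positive.max() / positive.min() > 3.0:
        logger.warning(
            "background windows have heterogeneous spread (%.3g..%.3g); "
            "the particle may not be centered",
            positive.min(),
            positive.max(),
        )
    pooled = np.concatenate(samples)
    return float(pooled.mean()), float(pooled.std())


def confidence_map(
    grid: DensityGrid,
    q: float = 0.01,
    resolutions_scan: list[float] | None = None,
) -> ConfidenceGrid:
    """FDR confidence map pooled over a resolution scan.

    For each resolution the map is low-pass filtered, background noise is
    re-estimated, right-tail p-values are computed under the noise Gaussian,
    and a Benjamini–Yekutieli adjustment (valid under dependence) is applied
    across all voxels.  The final confidence is the voxel-wise maximum of
    1 - adjusted q over the scan.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    scans = resolutions_scan or [None]
    nyquist = 2.0 * max(grid.voxel_size)
    base_mean, base_sd = estimate_noise(grid)  # also enforces the unmasked precondition

    best = np.zeros(grid.shape, dtype=float)
    used: list[float] = []
    for res in scans:
        if res is None:
            filtered = grid
            used.append(0.0)
        else:
            if res < nyquist:
                logger.warning("scan resolution %.2f Å below Nyquist; skipped", res)
                continue
            filtered = lowpass_filter(grid, res)
            used.append(float(res))
        mean, sd = estimate_noise(filtered)
        if sd == 0:
            raise ValueError("zero background spread; cannot form p-values")
        p = stats.norm.sf((filtered.values.ravel() - mean) / sd)
        _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_by")
        conf = 1.0 - p_adj.reshape(grid.shape)
        np.maximum(best, conf, out=best)
    if not used:
        raise ValueError("no usable resolution in the scan")
    return ConfidenceGrid(
        values=best,
        voxel_size=grid.voxel_size,
        origin=grid.origin,
        source_resolutions=used,
        noise_mean=base_mean,
        noise_sd=base_sd,
    )


def fdr_backbone_scores(
    model: AtomicModel,
    conf: ConfidenceGrid,
    params: BackboneScoreParams | None = None,
) -> "ResidueScoreSeries":
    """Fraction of each residue's backbone atoms in confident volume.

    Atom confidences are read by trilinear interpolation; an atom counts as
    confident when its confidence is at least 1 - q.  Residues without
    backbone atoms (ligands, waters) are left unscored.
    """
    from .local_fit import ResidueScoreSeries  # local import avoids a cycle

    params = params or BackboneScoreParams()
    threshold = 1.0 - params.q
    values: dict[ResidueKey, float] = {}
    flags: dict[ResidueKey, bool] = {}
    shape = np.array(conf.values.shape)
    for key in model.residues:
        atoms = backbone_atoms(model, key)
        if not atoms:
            logger.info("residue %s has no backbone atoms; unscored", key.label())
            continue
        idx = np.array([conf.coord_to_index(a.coord) for a in atoms]).T
        inside = np.all((idx >= 0) & (idx <= (shape - 1)[:, None]), axis=0)
        conf_at = np.zeros(len(atoms))
        if inside.any():
            conf_at[inside] = ndimage.map_coordinates(
                conf.values, idx[:, inside], order=1, mode="nearest"
            )
        score = float(np.mean(conf_at >= threshold))
        values[key] = score
        flags[key] = score < params.residue_cutoff
    if not values:
        raise ValueError("no residue could be scored (no backbone atoms found)")
    return ResidueScoreSeries(metric_name="fdr_backbone", values=values, outlier_flags=flags)


def overall_fdr_metric(series, cutoff: float = 0.9) -> float:
    """Fraction of scored residues with a backbone score strictly above the cutoff."""
    if not series.values:
        raise ValueError("empty score series")
    scores = np.array(list(series.values.values()))
    return float(np.mean(scores > cutoff))
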