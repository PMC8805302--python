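"""Global model-to-map agreement scores.

Implements the Fourier shell correlation (FSC) between a simulated and an
experimental map, its structure-factor-weighted average (FSCavg) up to the
reported resolution limit, real-space scores computed over above-contour
voxels (CCC, mutual information, overlap), ensemble-combined scores, and the
half-map comparison used to flag overfitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .map_simulation import SimulationParams, simulate_map
from .volumetric_io import ContourLevel, DegenerateMapError, DensityGrid, estimate_contour

logger = logging.getLogger(__name__)

__all__ = [
    "FscShell",
    "FscCurve",
    "GlobalFitScores",
    "EnsembleScores",
    "fsc_curve",
    "fsc_avg",
    "ccc",
    "mutual_information",
    "overlap",
    "combined_scores",
    "global_fit_scores",
    "halfmap_comparison",
]


@dataclass(frozen=True)
class FscShell:
    d_max: float  # coarse resolution bound (Å)
    d_min: float  # fine resolution bound (Å)
    n_terms: int
    fsc: float

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("shell requires d_min < d_max")
        if self.n_terms < 1:
            raise ValueError("shell requires n_terms >= 1")
        if not -1.0 <= self.fsc <= 1.0:
            raise ValueError("fsc outside [-1, 1]")


@dataclass
class FscCurve:
    shells: list[FscShell]
    resolution_limit: float

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d_max = np.array([s.d_max for s in self.shells])
        d_min = np.array([s.d_min for s in self.shells])
        n = np.array([s.n_terms for s in self.shells])
        f = np.array([s.fsc for s in self.shells])
        return d_max, d_min, n, f


@dataclass
class GlobalFitScores:
    fsc_avg: float
    ccc: float
    mi: float
    ov: float
    contour_model: ContourLevel
    contour_exp: ContourLevel


@dataclass
class EnsembleScores:
    scores: list[GlobalFitScores]
    ccc_ov: list[float] | None = None
    mi_ov: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.scores) < 3:
            raise ValueError("combined scores require three or more models")


def _check_geometry(a: DensityGrid, b: DensityGrid) -> None:
    if not a.same_geometry(b):
        raise ValueError("maps differ in grid geometry (shape/voxel/origin)")


def fsc_curve(
    map_a: DensityGrid,
    map_b: DensityGrid,
    n_shells: int | None = None,
    resolution_limit: float = 0.0,
) -> FscCurve:
    """Fourier shell correlation in equal-width frequency shells.

    Coefficients are taken from the Hermitian half-spectrum so each structure
    factor is counted once; the DC term is excluded from the first shell.
    Default shell count is half the smallest grid dimension, capped at 64.
    """
    _check_geometry(map_a, map_b)
    nx, ny, nz = map_a.shape
    if n_shells is None:
        n_shells = min(min(nx, ny, nz) // 2, 64)
    if n_shells < 2:
        raise ValueError("need at least 2 shells")

    A = np.fft.rfftn(map_a.values)
    B = np.fft.rfftn(map_b.values)
    vx, vy, vz = map_a.voxel_size
    fx = np.fft.fftfreq(nx, d=vx)
    fy = np.fft.fftfreq(ny, d=vy)
    fz = np.fft.rfftfreq(nz, d=vz)
    s = np.sqrt(fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2)

    s_max = min(0.5 / vx, 0.5 / vy, 0.5 / vz)  # fully sampled sphere only
    ds = s_max / n_shells
    shell_idx = np.floor(s / ds).astype(int)  # 0 .. n_shells-1 inside s_max
    valid = (s > 0) & (s <= s_max)

    shells: list[FscShell] = []
    for k in range(n_shells):
        mask = valid & (shell_idx == np.minimum(k, n_shells - 1)) & (s > k * ds) & (
            s <= (k + 1) * ds
        )
        n_terms = int(mask.sum())
        if n_terms == 0:
            continue
        a = A[mask]
        b = B[mask]
        num = float(np.real(np.sum(a * np.conj(b))))
        den = float(np.sqrt(np.sum(np.abs(a) ** 2) * np.sum(np.abs(b) ** 2)))
        corr = 0.0 if den == 0 else float(np.clip(num / den, -1.0, 1.0))
        s_lo, s_hi = k * ds, (k + 1) * ds
        d_max = np.inf if s_lo == 0 else 1.0 / s_lo
        shells.append(FscShell(d_max=d_max, d_min=1.0 / s_hi, n_terms=n_terms, fsc=corr))
    return FscCurve(shells=shells, resolution_limit=resolution_limit)


def fsc_avg(curve: FscCurve) -> float:
    """FSC averaged over shells, weighted by structure-factor count, using only
    shells coarser than the resolution limit (d_min >= limit)."""
    if not curve.shells:
        raise ValueError("empty FSC curve")
    kept = [s for s in curve.shells if s.d_min >= curve.resolution_limit]
    if not kept:
        logger.warning(
            "resolution limit %.2f Å finer than the finest shell; using all shells",
            curve.resolution_limit,
        )
        kept = curve.shells
    n = np.array([s.n_terms for s in kept], dtype=float)
    f = np.array([s.fsc for s in kept])
    return float(np.sum(n * f) / np.sum(n))


def _above(grid: DensityGrid, contour: ContourLevel) -> np.ndarray:
    return grid.values >= contour.level


def ccc(
    map_a: DensityGrid,
    map_b: DensityGrid,
    contour_a: ContourLevel,
    contour_b: ContourLevel,
) -> float:
    """Pearson cross-correlation over the union of above-contour voxel sets."""
    _check_geometry(map_a, map_b)
    mask = _above(map_a, contour_a) | _above(map_b, contour_b)
    if mask.sum() < 2:
        raise DegenerateMapError("fewer than 2 voxels above either contour")
    a = map_a.values[mask]
    b = map_b.values[mask]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise DegenerateMapError("constant values over the contoured region")
    return float(np.clip(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb), -1.0, 1.0))


def mutual_information(
    map_a: DensityGrid,
    map_b: DensityGrid,
    contour_a: ContourLevel,
    contour_b: ContourLevel,
    bins: int = 20,
) -> float:
    """Mutual information (nats) of the joint binned density distribution.

    Bin edges are equal-width over each map's above-contour value range;
    the joint histogram is accumulated over the union voxel set.
    """
    _check_geometry(map_a, map_b)
    if bins < 2:
        raise ValueError("need at least 2 bins")
    in_a = _above(map_a, contour_a)
    in_b = _above(map_b, contour_b)
    mask = in_a | in_b
    if not mask.any():
        raise DegenerateMapError("no voxels above either contour")

    def _edges(values: np.ndarray, sel: np.ndarray) -> np.ndarray:
        v = values[sel] if sel.any() else values[mask]
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            hi = lo + 1e-12
        return np.linspace(lo, hi, bins + 1)

    ea = _edges(map_a.values, in_a)
    eb = _edges(map_b.values, in_b)
    a = np.clip(map_a.values[mask], ea[0], ea[-1])
    b = np.clip(map_b.values[mask], eb[0], eb[-1])
    joint, _, _ = np.histogram2d(a, b, bins=[ea, eb])
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def overlap(
    map_a: DensityGrid,
    map_b: DensityGrid,
    contour_a: ContourLevel,
    contour_b: ContourLevel,
) -> float:
    """Fraction of the smaller above-contour volume shared by both maps."""
    _check_geometry(map_a, map_b)
    in_a = _above(map_a, contour_a)
    in_b = _above(map_b, contour_b)
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na == 0 or nb == 0:
        logger.warning("empty above-contour set; overlap reported as 0")
        return 0.0
    return float((in_a & in_b).sum() / min(na, nb))


def combined_scores(ensemble: EnsembleScores) -> EnsembleScores:
    """Fill CCC_OV and MI_OV: each raw score is standardized to zero mean and
    unit spread across the ensemble (constant scores map to zeros), then the
    standardized overlap is added to the standardized CCC or MI."""

    def _z(values: list[float]) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        sd = v.std()  # population sd across models
        if sd <= 1e-12 * max(1.0, float(np.abs(v).max())):  # constant up to roundoff
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    z_ccc = _z([s.ccc for s in ensemble.scores])
    z_mi = _z([s.mi for s in ensemble.scores])
    z_ov = _z([s.ov for s in ensemble.scores])
    return EnsembleScores(
        scores=ensemble.scores,
        ccc_ov=list(z_ccc + z_ov),
        mi_ov=list(z_mi + z_ov),
    )


def global_fit_scores(
    sim_map: DensityGrid,
    exp_map: DensityGrid,
    resolution_limit: float,
    contour_exp: ContourLevel | None = None,
    n_shells: int | None = None,
    mi_bins: int = 20,
) -> tuple[GlobalFitScores, FscCurve]:
    """All global scores of one simulated map against one experimental map."""
    c_exp = contour_exp or estimate_contour(exp_map)
    c_sim = estimate_contour(sim_map)
    curve = fsc_curve(sim_map, exp_map, n_shells=n_shells, resolution_limit=resolution_limit)
    scores = GlobalFitScores(
        fsc_avg=fsc_avg(curve),
        ccc=ccc(sim_map, exp_map, c_sim, c_exp),
        mi=mutual_information(sim_map, exp_map, c_sim, c_exp, bins=mi_bins),
        ov=overlap(sim_map, exp_map, c_sim, c_exp),
        contour_model=c_sim,
        contour_exp=c_exp,
    )
    return scores, curve


def halfmap_comparison(
    model,
    map_1: DensityGrid,
    map_2: DensityGrid,
    params: SimulationParams,
    contour_1: ContourLevel | None = None,
    contour_2: ContourLevel | None = None,
) -> tuple[GlobalFitScores, GlobalFitScores, float]:
    """Score a model against two (half) maps; a large positive FSCavg
    difference (map 1 minus map 2) flags overfitting to map 1."""
    _check_geometry(map_1, map_2)
    sim = simulate_map(model, replace(params, grid_template=map_1))
    s1, _ = global_fit_scores(sim, map_1, params.resolution, contour_exp=contour_1)
    s2, _ = global_fit_scores(sim, map_2, params.resolution, contour_exp=contour_2)
    return s1, s2, s1.fsc_avg - s2.fsc_avg
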