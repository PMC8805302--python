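"""Map-independent model sanity checks.

Two quick checks that need no density map: the shape of the atomic B-factor
distribution (multiple peaks hint at partial occupancies, domain motions or
inconsistent B refinement; an all-equal distribution means the B factors were
never refined), and a simplified steric-clash count over van der Waals radii.
The clash check is a deliberately lightweight stand-in for a full
MolProbity-style clashscore and is labelled as such in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from scipy.spatial import cKDTree

from .model_io import Atom, AtomicModel, ResidueKey

logger = logging.getLogger(__name__)

__all__ = ["BFactorSummary", "Clash", "bfactor_summary", "clash_list", "VDW_RADII"]

# fixed published vdW radii (Å); elements absent from the table fall back to C
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

MIN_ATOMS_FOR_PEAKS = 10
PEAK_PROMINENCE_FRACTION = 0.05
KDE_POINTS = 256


@dataclass
class BFactorSummary:
    n_atoms: int
    mean: float
    sd: float
    min: float
    max: float
    peak_positions: list[float]
    multimodal_warning: bool
    unrefined_warning: bool = False
    kde_grid: np.ndarray | None = None
    kde_density: np.ndarray | None = None


@dataclass(frozen=True)
class Clash:
    atom_a: tuple[ResidueKey, str]
    atom_b: tuple[ResidueKey, str]
    overlap: float


def bfactor_summary(model: AtomicModel) -> BFactorSummary:
    """Summarize the atomic B-factor distribution and detect multiple peaks.

    Peaks are local maxima of a Gaussian kernel density estimate (Silverman
    bandwidth, 256 evaluation points) with prominence of at least 5% of the
    KDE maximum.  Fewer than 10 atoms: summary statistics only.  All-equal
    B factors raise the distinct unrefined-B warning.
    """
    b = np.array([a.b_factor for _, a in model.atoms()], dtype=float)
    base = dict(
        n_atoms=int(b.size),
        mean=float(b.mean()),
        sd=float(b.std()),
        min=float(b.min()),
        max=float(b.max()),
    )
    if b.size < MIN_ATOMS_FOR_PEAKS:
        logger.info("only %d atoms; skipping B-factor peak analysis", b.size)
        return BFactorSummary(peak_positions=[], multimodal_warning=False, **base)
    if b.std() == 0.0:
        logger.warning("all B factors equal (%.1f Å²): B factors appear unrefined", b[0])
        return BFactorSummary(
            peak_positions=[float(b[0])],
            multimodal_warning=False,
            unrefined_warning=True,
            **base,
        )
    kde = stats.gaussian_kde(b, bw_method="silverman")
    bw = kde.factor * b.std()
    grid = np.linspace(b.min() - 3 * bw, b.max() + 3 * bw, KDE_POINTS)
    density = kde(grid)
    peaks, _ = signal.find_peaks(
        density, prominence=PEAK_PROMINENCE_FRACTION * density.max()
    )
    positions = sorted(float(grid[i]) for i in peaks)
    multimodal = len(positions) >= 2
    if multimodal:
        logger.warning(
            "B-factor distribution has %d peaks at %s Å²: possible partial "
            "occupancies, domain motions or inconsistent B refinement",
            len(positions),
            ", ".join(f"{p:.1f}" for p in positions),
        )
    return BFactorSummary(
        peak_positions=positions,
        multimodal_warning=multimodal,
        kde_grid=grid,
        kde_density=density,
        **base,
    )


# bond-graph hop counts to/from the inter-residue link atoms, for the standard
# protein backbone (link C(i)-N(i+1)) and nucleic backbone (link O3'(i)-P(i+1))
_HOPS_TO_C = {"C": 0, "CA": 1, "O": 1, "N": 2, "CB": 2, "OXT": 1}
_HOPS_FROM_N = {"N": 0, "CA": 1, "C": 2, "CB": 2, "O": 3, "H": 1}
_HOPS_TO_O3 = {"O3'": 0, "C3'": 1, "C4'": 2, "C2'": 2}
_HOPS_FROM_P = {"P": 0, "OP1": 1, "OP2": 1, "O5'": 1, "C5'": 2}


def _excluded(key_a: ResidueKey, name_a: str, key_b: ResidueKey, name_b: str) -> bool:
    """Covalently related pairs that must not count as clashes: any pair inside
    one residue, and pairs within three bonds across the backbone link between
    sequence-adjacent residues (1-2, 1-3 and 1-4 through the peptide or
    phosphodiester bond).  Atom names outside the standard backbone count as
    distant, so genuine side-chain contacts are kept."""
    if key_a == key_b:
        return True
    if key_a.chain_id != key_b.chain_id:
        return False
    if key_b[:3] < key_a[:3]:
        key_a, name_a, key_b, name_b = key_b, name_b, key_a, name_a
    if key_b.seq_num - key_a.seq_num != 1:
        return False
    for to_link, from_link in ((_HOPS_TO_C, _HOPS_FROM_N), (_HOPS_TO_O3, _HOPS_FROM_P)):
        if name_a in to_link and name_b in from_link:
            if to_link[name_a] + 1 + from_link[name_b] <= 3:
                return True
    return False


def clash_list(
    model: AtomicModel, overlap_cutoff: float = 0.4
) -> tuple[list[Clash], float]:
    """Serious steric overlaps and the clashes-per-1000-atoms rate.

    A pair clashes when the sum of vdW radii exceeds the distance by at least
    ``overlap_cutoff`` (Å).  Covalently linked pairs (within a residue or
    across a peptide bond) are excluded.  Each pair is reported once.
    """
    entries: list[tuple[ResidueKey, Atom]] = list(model.atoms())
    if not entries:
        return [], 0.0
    coords = np.array([a.coord for _, a in entries])
    radii = np.array([VDW_RADII.get(a.element.upper(), VDW_RADII["C"]) for _, a in entries])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.0 * radii.max(), output_type="ndarray")

    clashes: list[Clash] = []
    for i, j in pairs:
        key_i, atom_i = entries[i]
        key_j, atom_j = entries[j]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        ov = radii[i] + radii[j] - d
        if ov < overlap_cutoff:
            continue
        if _excluded(key_i, atom_i.name, key_j, atom_j.name):
            continue
        clashes.append(Clash((key_i, atom_i.name), (key_j, atom_j.name), float(ov)))
    clashes.sort(key=lambda c: (c.atom_a[0][:3], c.atom_a[1], c.atom_b[0][:3], c.atom_b[1]))
    rate = 1000.0 * len(clashes) / len(entries)
    return clashes, rate
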