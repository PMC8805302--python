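"""Deterministic synthetic models and maps for testing every score.

Polyalanine chains are built from ideal internal coordinates (N–CA 1.46,
CA–C 1.52, C–N 1.33 Å; helical or extended torsions), given per-atom B
factors, and turned into simulated density with optional additive Gaussian
background noise — a desk-scale stand-in for deposited model/map pairs.
Everything is reproducible from the integer seed in the spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .map_simulation import SimulationParams, simulate_map
from .model_io import Atom, AtomicModel, ResidueKey
from .volumetric_io import DensityGrid

__all__ = [
    "FixtureSpec",
    "make_model",
    "make_map_pair",
    "perturb_model",
    "write_fixture_pdb",
    "write_fixture_mmcif",
]

# ideal backbone internal coordinates
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
BOND_CA_CB = 1.53
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

TORSIONS = {
    "ideal_helix": (-57.8, -47.0),
    "extended": (-139.0, 135.0),
}


@dataclass
class FixtureSpec:
    """Conditions of one synthetic model/map pair.

    noise_sd is expressed as a fraction of the clean map's peak value;
    perturbations are (ResidueKey, displacement) with the displacement either
    a 3-vector (Å) or a scalar magnitude applied along +x.
    """

    n_residues: int = 20
    geometry: str = "ideal_helix"
    resolution: float = 3.0
    noise_sd: float = 0.2
    voxel_size: float = 1.0
    seed: int = 0
    perturbations: list = field(default_factory=list)
    b_factor_mean: float = 30.0
    b_factor_sd: float = 5.0
    pad: float = 10.0

    def __post_init__(self) -> None:
        if self.geometry not in ("ideal_helix", "extended", "two_chain"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-of-reference-frame placement of atom d from atoms
    a-b-c, with bond |cd|, angle b-c-d and torsion a-b-c-d (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(chain_id: str, n_residues: int, phi: float, psi: float, rng: np.random.Generator, b_mean: float, b_sd: float) -> dict[ResidueKey, list[Atom]]:
    backbone: list[dict[str, np.ndarray]] = []
    for i in range(n_residues):
        if i == 0:
            N = np.zeros(3)
            CA = np.array([BOND_N_CA, 0.0, 0.0])
            ang = math.radians(ANGLE_N_CA_C)
            C = CA + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            prev = backbone[i - 1]
            N = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
            CA = _place_atom(prev["CA"], prev["C"], N, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            C = _place_atom(prev["C"], N, CA, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append({"N": N, "CA": CA, "C": C})
    for i, res in enumerate(backbone):
        # carbonyl O opposite the next N: dihedral N-CA-C-O = psi + 180
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        # torsion C-N-CA-CB = -123 deg gives L-chirality (positive triple
        # product of N-CA, C-CA, CB-CA)
        res["CB"] = _place_atom(res["C"], res["N"], res["CA"], BOND_CA_CB, 110.5, -123.0)

    residues: dict[ResidueKey, list[Atom]] = {}
    for i, res in enumerate(backbone):
        key = ResidueKey(chain_id=chain_id, seq_num=i + 1, insertion_code="", res_name="ALA")
        atoms = []
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")):
            b = float(max(1.0, rng.normal(b_mean, b_sd)))
            atoms.append(Atom(name=name, element=element, coord=tuple(res[name]), b_factor=b))
        residues[key] = atoms
    return residues


def make_model(spec: FixtureSpec) -> AtomicModel:
    """Deterministic polyalanine model for the requested geometry."""
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "two_chain":
        phi, psi = TORSIONS["ideal_helix"]
        residues = _build_chain("A", spec.n_residues, phi, psi, rng, spec.b_factor_mean, spec.b_factor_sd)
        chain_b = _build_chain("B", spec.n_residues, phi, psi, rng, spec.b_factor_mean, spec.b_factor_sd)
        shift = np.array([0.0, 12.0, 0.0])
        for key, atoms in chain_b.items():
            residues[key] = [replace(a, coord=tuple(np.array(a.coord) + shift)) for a in atoms]
    else:
        phi, psi = TORSIONS[spec.geometry]
        residues = _build_chain("A", spec.n_residues, phi, psi, rng, spec.b_factor_mean, spec.b_factor_sd)
    return AtomicModel(residues=residues, title=f"synthetic {spec.geometry}")


def make_map_pair(model: AtomicModel, spec: FixtureSpec) -> tuple[DensityGrid, DensityGrid]:
    """Clean simulated map on a padded grid, plus a noisy copy.

    The grid extends ``spec.pad`` Å beyond the model bounding box; noise is
    i.i.d. Gaussian with sd equal to ``spec.noise_sd`` times the clean peak.
    """
    coords = model.coordinates()
    lo = coords.min(axis=0) - spec.pad
    hi = coords.max(axis=0) + spec.pad
    shape = tuple(int(math.ceil((hi[k] - lo[k]) / spec.voxel_size)) + 1 for k in range(3))
    template = DensityGrid(
        np.zeros(shape), (spec.voxel_size,) * 3, tuple(lo)
    )
    params = SimulationParams(resolution=spec.resolution, grid_template=template)
    clean = simulate_map(model, params)
    if spec.noise_sd == 0:
        return clean, clean
    rng = np.random.default_rng(spec.seed + 1)
    sd = spec.noise_sd * float(clean.values.max())
    noisy = clean.with_values(clean.values + rng.normal(0.0, sd, size=clean.shape))
    return clean, noisy


def perturb_model(model: AtomicModel, perturbations) -> AtomicModel:
    """Rigidly translate the listed residues; everything else is untouched."""
    moves: dict[ResidueKey, np.ndarray] = {}
    for key, disp in perturbations:
        if key not in model.residues:
            raise KeyError(f"unknown residue {key.label()}")
        vec = np.array([disp, 0.0, 0.0]) if np.isscalar(disp) else np.asarray(disp, dtype=float)
        moves[key] = vec
    residues = {
        key: (
            [replace(a, coord=tuple(np.array(a.coord) + moves[key])) for a in atoms]
            if key in moves
            else list(atoms)
        )
        for key, atoms in model.residues.items()
    }
    return AtomicModel(residues=residues, title=model.title + " (perturbed)")


def _to_gemmi(model: AtomicModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.title or "synthetic"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for key, atoms in model.residues.items():
        chain = chains.get(key.chain_id)
        if chain is None:
            chain = gemmi.Chain(key.chain_id)
            chains[key.chain_id] = chain
        res = gemmi.Residue()
        res.name = key.res_name
        res.seqid = gemmi.SeqId(key.seq_num, key.insertion_code or " ")
        for a in atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.b_iso = a.b_factor
            ga.occ = a.occupancy
            res.add_atom(ga)
        chain.add_residue(res)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    return st


def write_fixture_pdb(model: AtomicModel, path) -> None:
    _to_gemmi(model).write_pdb(str(path))


def write_fixture_mmcif(model: AtomicModel, path) -> None:
    _to_gemmi(model).make_mmcif_document().write_file(str(path))
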