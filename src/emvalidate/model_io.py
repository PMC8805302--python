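"""Atomic-model parsing into a uniform in-memory representation.

PDB and mmCIF files are parsed (via gemmi) into an :class:`AtomicModel`:
an ordered mapping from :class:`ResidueKey` to atom lists.  Alternate
conformations are collapsed to the highest-occupancy conformer so that each
residue has a single spatial footprint for per-residue scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "ResidueKey",
    "AtomicModel",
    "ModelFormatError",
    "read_model",
    "backbone_atoms",
    "ca_coordinates",
    "PROTEIN_BACKBONE",
    "NUCLEIC_BACKBONE",
]

PROTEIN_BACKBONE = ("N", "CA", "C", "O")
NUCLEIC_BACKBONE = ("P", "C3'", "C4'", "C5'", "O3'", "O5'")
_WATER_NAMES = {"HOH", "WAT", "DOD"}


class ModelFormatError(ValueError):
    """The file is not a parseable PDB/mmCIF model."""


class ResidueKey(NamedTuple):
    """Identity of one residue; ordering is (chain, seq_num, insertion_code)."""

    chain_id: str
    seq_num: int
    insertion_code: str
    res_name: str

    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}/{self.seq_num}{icode}/{self.res_name}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    b_factor: float = 0.0
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.coord)
        if not all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: non-finite coordinates {c}")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B factor")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy outside [0,1]")
        object.__setattr__(self, "coord", c)


@dataclass
class AtomicModel:
    """Ordered residues of one structure model."""

    residues: dict[ResidueKey, list[Atom]]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("model has no residues")
        for key, atoms in self.residues.items():
            if not atoms:
                raise ValueError(f"residue {key.label()} has no atoms")

    def __iter__(self) -> Iterator[ResidueKey]:
        return iter(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(a) for a in self.residues.values())

    def atoms(self) -> Iterator[tuple[ResidueKey, Atom]]:
        for key, atom_list in self.residues.items():
            for atom in atom_list:
                yield key, atom

    def coordinates(self) -> np.ndarray:
        return np.array([a.coord for _, a in self.atoms()], dtype=float)

    def get_atom(self, key: ResidueKey, name: str) -> Atom | None:
        for atom in self.residues.get(key, ()):
            if atom.name == name:
                return atom
        return None


def _is_amino(res_name: str) -> bool:
    info = gemmi.find_tabulated_residue(res_name)
    return bool(info and info.is_amino_acid())


def _is_nucleic(res_name: str) -> bool:
    info = gemmi.find_tabulated_residue(res_name)
    return bool(info and info.is_nucleic_acid())


def read_model(path) -> AtomicModel:
    """Parse a PDB or mmCIF file (format auto-detected).

    Altlocs are collapsed to the highest-occupancy conformer (ties broken by
    file order); waters and other het records keep an ``is_hetero`` flag.
    Only the first model of a multi-model file is used.
    """
    path = Path(path)
    if not path.is_file():
        raise ModelFormatError(f"no such model file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ModelFormatError(f"{path} holds no model")
    if len(st) > 1:
        logger.warning("%s holds %d models; using the first", path, len(st))

    residues: dict[ResidueKey, list[Atom]] = {}
    for chain in st[0]:
        for res in chain:
            key = ResidueKey(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                insertion_code=(res.seqid.icode or " ").strip() or "",
                res_name=res.name,
            )
            is_het = res.het_flag == "H"
            # collapse altlocs: best occupancy per atom name, first wins ties
            best: dict[str, Atom] = {}
            for a in res:
                atom = Atom(
                    name=a.name,
                    element=a.element.name,
                    coord=(a.pos.x, a.pos.y, a.pos.z),
                    b_factor=max(0.0, a.b_iso),
                    occupancy=float(np.clip(a.occ, 0.0, 1.0)),
                    is_hetero=is_het,
                )
                prev = best.get(a.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    best[a.name] = atom
            if not best:
                continue
            if key in residues:
                logger.warning("duplicate residue %s; merging atoms", key.label())
                residues[key].extend(best.values())
            else:
                residues[key] = list(best.values())

    if not residues:
        raise ModelFormatError(f"{path} parsed to an empty model")
    if all(k.res_name in _WATER_NAMES for k in residues):
        logger.warning("%s contains only water molecules", path)
    return AtomicModel(residues=residues, title=st.name or path.stem)


def backbone_atoms(model: AtomicModel, residue: ResidueKey) -> list[Atom]:
    """Backbone atoms of one residue: N/CA/C/O for amino acids,
    P/C3'/C4'/C5'/O3'/O5' for nucleotides, empty for anything else."""
    if residue not in model.residues:
        raise KeyError(f"unknown residue {residue.label()}")
    if _is_amino(residue.res_name):
        names = PROTEIN_BACKBONE
    elif _is_nucleic(residue.res_name):
        names = NUCLEIC_BACKBONE
    else:
        return []
    wanted = {n.replace("'", "*") for n in names} | set(names)
    return [a for a in model.residues[residue] if a.name in wanted]


def ca_coordinates(model: AtomicModel) -> dict[ResidueKey, tuple[float, float, float]]:
    """One reference coordinate per residue: CA, falling back to P for
    nucleotides.  Residues with neither are omitted (logged)."""
    out: dict[ResidueKey, tuple[float, float, float]] = {}
    for key in model.residues:
        atom = model.get_atom(key, "CA") or model.get_atom(key, "P")
        if atom is None:
            logger.info("residue %s lacks CA/P; omitted from coordinate map", key.label())
            continue
        out[key] = atom.coord
    return out
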