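"""TRIPOS MOL2 structure I/O and chemical feature perception.

The MOL2 dialect handled here is the narrow machine-generated one used for
trajectory frames and pose files: ``MOLECULE``, ``ATOM`` and ``BOND`` records,
``ar``/``am`` bond orders accepted, ``SUBSTRUCTURE`` ignored beyond residue
bookkeeping. A dedicated reader/writer is used (rather than a general
chemistry toolkit) because downstream IPA files reuse the ATOM record for
pseudo-atoms that no sanitising parser would accept, and because byte-level
round-trip fidelity of SYBYL types is a tested contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import chem_rules

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "MolecularStructure",
    "ComplexFrame",
    "AromaticRing",
    "ChemicalAnnotation",
    "Mol2ParseError",
    "read_mol2",
    "write_mol2",
    "perceive_chemistry",
    "find_aromatic_rings",
]

BOND_ORDERS = {"1", "2", "3", "ar", "am", "du", "un", "nc"}


class Mol2ParseError(ValueError):
    """Raised on malformed MOL2 records; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class Atom:
    """One ATOM record."""

    atom_id: int
    name: str
    sybyl_type: str
    coords: np.ndarray
    partial_charge: float = 0.0
    residue_name: str = "UNK"
    residue_number: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_id}: coords must be a finite 3-vector")

    @property
    def element(self) -> str:
        return chem_rules.element_of(self.sybyl_type)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class MolecularStructure:
    """Atoms plus bonds, in file order."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    mol_name: str = "MOL"

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValueError("atom_ids must be unique")
        known = set(ids)
        for a, b, order in self.bonds:
            if a not in known or b not in known:
                raise ValueError(f"bond ({a}, {b}) references unknown atom")
            if order not in BOND_ORDERS:
                raise ValueError(f"unknown bond order {order!r}")

    def atom(self, atom_id: int) -> Atom:
        try:
            return self._by_id[atom_id]
        except AttributeError:
            self._by_id = {a.atom_id: a for a in self.atoms}
            return self._by_id[atom_id]

    def neighbours(self, atom_id: int) -> list[Atom]:
        out = []
        for a, b, _ in self.bonds:
            if a == atom_id:
                out.append(self.atom(b))
            elif b == atom_id:
                out.append(self.atom(a))
        return out

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.coords for a in self.atoms])


@dataclass
class ComplexFrame:
    """One protein/ligand pair, e.g. a trajectory frame or a docking pose."""

    protein: MolecularStructure
    ligand: MolecularStructure
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if not self.ligand.heavy_atoms():
            raise ValueError("ligand must contain at least one heavy atom")


@dataclass
class AromaticRing:
    member_ids: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class ChemicalAnnotation:
    """Per-atom feature flags plus perceived aromatic rings.

    All flag sets hold atom ids and refer to heavy atoms only. Donor atoms
    additionally record their attached explicit hydrogens, which the
    hydrogen-bond angle test consumes.
    """

    hbond_donor: set[int] = field(default_factory=set)
    hbond_acceptor: set[int] = field(default_factory=set)
    cation: set[int] = field(default_factory=set)
    anion: set[int] = field(default_factory=set)
    hydrophobic: set[int] = field(default_factory=set)
    metal: set[int] = field(default_factory=set)
    donor_hydrogens: dict[int, list[int]] = field(default_factory=dict)
    aromatic_rings: list[AromaticRing] = field(default_factory=list)


# ---------------------------------------------------------------------------
# MOL2 I/O
# ---------------------------------------------------------------------------

def read_mol2(source) -> MolecularStructure:
    """Parse a single-molecule MOL2 document.

    Parameters
    ----------
    source
        A string of MOL2 text, an open text stream, or a filesystem path.

    Returns
    -------
    MolecularStructure
        Atoms in file order; coordinates in Angstrom; partial charges parsed
        when the column is present, else 0. A missing BOND section yields an
        empty bond list with a logged warning.
    """
    text = _as_text(source)
    lines = text.splitlines()
    section = None
    mol_header: list[str] = []
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, str]] = []
    saw_bond_section = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            if section == "BOND":
                saw_bond_section = True
            continue
        if section == "MOLECULE":
            mol_header.append(line)
        elif section == "ATOM":
            atoms.append(_parse_atom(line, lineno))
        elif section == "BOND":
            bonds.append(_parse_bond(line, lineno))
        # other sections (SUBSTRUCTURE etc.) are ignored

    if not mol_header and not atoms:
        raise Mol2ParseError("no @<TRIPOS>MOLECULE section found")
    name = mol_header[0] if mol_header else "MOL"
    if not saw_bond_section and atoms:
        logger.warning("mol2 %r has no @<TRIPOS>BOND section", name)
    return MolecularStructure(atoms=atoms, bonds=bonds, mol_name=name)


def _parse_atom(line: str, lineno: int) -> Atom:
    fields = line.split()
    if len(fields) < 6:
        raise Mol2ParseError(f"ATOM record has {len(fields)} fields, expected >= 6", lineno)
    try:
        atom_id = int(fields[0])
        coords = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
        sybyl = fields[5]
        resnum = int(fields[6]) if len(fields) > 6 else 1
        resname = fields[7] if len(fields) > 7 else "UNK"
        charge = float(fields[8]) if len(fields) > 8 else 0.0
    except ValueError as exc:
        raise Mol2ParseError(f"malformed ATOM record: {exc}", lineno) from None
    return Atom(
        atom_id=atom_id,
        name=fields[1],
        sybyl_type=sybyl,
        coords=coords,
        partial_charge=charge,
        residue_name=resname,
        residue_number=resnum,
    )


def _parse_bond(line: str, lineno: int) -> tuple[int, int, str]:
    fields = line.split()
    if len(fields) < 4:
        raise Mol2ParseError(f"BOND record has {len(fields)} fields, expected >= 4", lineno)
    try:
        a, b = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise Mol2ParseError(f"malformed BOND record: {exc}", lineno) from None
    order = fields[3]
    if order not in BOND_ORDERS:
        raise Mol2ParseError(f"unknown bond order {order!r}", lineno)
    return (a, b, order)


def write_mol2(structure: MolecularStructure) -> str:
    """Serialise a structure to MOL2 text (coordinates with 4 decimals)."""
    out = ["@<TRIPOS>MOLECULE", structure.mol_name,
           f"{len(structure.atoms):d} {len(structure.bonds):d} 0 0 0",
           "SMALL", "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for a in structure.atoms:
        out.append(
            f"{a.atom_id:>7d} {a.name:<8s} {a.coords[0]:>10.4f} {a.coords[1]:>10.4f} "
            f"{a.coords[2]:>10.4f} {a.sybyl_type:<8s} {a.residue_number:>4d} "
            f"{a.residue_name:<8s} {a.partial_charge:>10.4f}"
        )
    out.append("@<TRIPOS>BOND")
    for i, (a, b, order) in enumerate(structure.bonds, start=1):
        out.append(f"{i:>6d} {a:>5d} {b:>5d} {order:>4s}")
    return "\n".join(out) + "\n"


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "@<TRIPOS>" in text:
        return text
    with open(text, "r") as handle:
        return handle.read()


# ---------------------------------------------------------------------------
# Chemical perception
# ---------------------------------------------------------------------------

def perceive_chemistry(structure: MolecularStructure) -> ChemicalAnnotation:
    """Apply the frozen rule table (:mod:`igocsvm.chem_rules`) to a structure.

    Deterministic in types and bonds only; coordinates play no role. Unknown
    SYBYL types receive no flags and are logged.
    """
    ann = ChemicalAnnotation()
    rules = chem_rules
    for atom in structure.atoms:
        if atom.is_hydrogen:
            continue
        el = atom.element
        typ = atom.sybyl_type
        neighbours = structure.neighbours(atom.atom_id)
        hydrogens = [n.atom_id for n in neighbours if n.is_hydrogen]
        heavy_nb = [n for n in neighbours if not n.is_hydrogen]

        known = False
        if el in rules.METAL_ELEMENTS:
            ann.metal.add(atom.atom_id)
            ann.cation.add(atom.atom_id)
            known = True
        if el in rules.HYDROPHOBIC_ELEMENTS:
            ann.hydrophobic.add(atom.atom_id)
            known = True
        if el in rules.DONOR_ELEMENTS:
            known = True
            if hydrogens or typ in rules.ALWAYS_DONOR_TYPES:
                ann.hbond_donor.add(atom.atom_id)
                ann.donor_hydrogens[atom.atom_id] = hydrogens
        if typ in rules.ACCEPTOR_TYPES:
            known = True
            if not (typ in rules.ACCEPTOR_TYPES_NO_H and hydrogens):
                ann.hbond_acceptor.add(atom.atom_id)
        if typ in rules.CATION_TYPES:
            ann.cation.add(atom.atom_id)
            known = True
        if el == "N" and any(n.sybyl_type in rules.CATION_NEIGHBOUR_TYPES for n in heavy_nb):
            ann.cation.add(atom.atom_id)
            known = True
        if typ in rules.ANION_TYPES:
            ann.anion.add(atom.atom_id)
            known = True
        if el == "O" and any(n.sybyl_type in rules.ANION_NEIGHBOUR_TYPES for n in heavy_nb):
            ann.anion.add(atom.atom_id)
            known = True
        if el in {"P", "S", "F", "Cl", "Br", "I", "B", "Si", "Se"} or typ in rules.AROMATIC_TYPES:
            known = True
        if not known:
            logger.warning("atom %d: unknown sybyl type %r, no flags assigned",
                           atom.atom_id, typ)
    ann.aromatic_rings = find_aromatic_rings(structure)
    return ann


def find_aromatic_rings(structure: MolecularStructure) -> list[AromaticRing]:
    """Enumerate 5/6-membered cycles of aromatic-typed atoms.

    Returns each ring once with its centroid (mean of member coordinates) and
    unit normal (principal axis orthogonal to the best-fit plane).
    """
    aromatic_ids = {a.atom_id for a in structure.atoms
                    if a.sybyl_type in chem_rules.AROMATIC_TYPES}
    if not aromatic_ids:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(aromatic_ids)
    for a, b, _ in structure.bonds:
        if a in aromatic_ids and b in aromatic_ids:
            graph.add_edge(a, b)

    rings: list[AromaticRing] = []
    seen: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(graph):
        if len(cycle) not in chem_rules.AROMATIC_RING_SIZES:
            continue
        key = frozenset(cycle)
        if key in seen:
            continue
        seen.add(key)
        coords = np.vstack([structure.atom(i).coords for i in cycle])
        centroid = coords.mean(axis=0)
        # smallest-singular-vector of the centred coordinates = plane normal
        _, _, vt = np.linalg.svd(coords - centroid)
        normal = vt[-1]
        normal = normal / np.linalg.norm(normal)
        rings.append(AromaticRing(tuple(sorted(cycle)), centroid, normal))
    rings.sort(key=lambda r: r.member_ids)
    return rings


def ring_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle (degrees) between two ring planes from their normals."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(min(1.0, c)))
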