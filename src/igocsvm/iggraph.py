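"""Complete, labeled, distance-weighted interaction graphs (IGs).

Each interaction triplet contributes three nodes (ligand, protein, centre),
labeled by interaction type and role. Every node pair is connected; the edge
weight is the Euclidean distance rounded half-up to the nearest Angstrom,
stored as deci-Angstrom integers so that all later shortest-path arithmetic
is exact. A pair of overlapping pseudo-atoms (rounded distance 0, i.e.
closer than 0.5 A) keeps an edge of weight 1 deci-A.

The Polar variant of a graph is obtained upstream of construction by
dropping hydrophobic triplets (:func:`filter_polar`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .interactions import ITYPES, InteractionTriplet
from .structio import Atom, MolecularStructure, read_mol2, write_mol2

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "NodeLabel",
    "InteractionGraph",
    "EmptyGraphError",
    "build_graph",
    "filter_polar",
    "read_ipa",
    "write_ipa",
]

#: Role order within a triplet and in the graph node sequence.
ROLES = ("ligand", "protein", "centre")

_ROLE_CODE = {"ligand": "L", "protein": "P", "centre": "C"}
_CODE_ROLE = {v: k for k, v in _ROLE_CODE.items()}


class NodeLabel(NamedTuple):
    """(interaction type, role) — 7 x 3 = 21 possible labels."""

    itype: str
    role: str

    def sort_key(self) -> tuple[int, int]:
        return (ITYPES.index(self.itype), ROLES.index(self.role))


class EmptyGraphError(ValueError):
    """Raised when a graph is requested for an empty triplet list."""


@dataclass
class InteractionGraph:
    """Node labels plus a symmetric integer weight matrix in deci-Angstrom."""

    labels: list[NodeLabel]
    weights: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.weights = np.asarray(self.weights, dtype=np.int64)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match label count")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        off = self.weights[~np.eye(n, dtype=bool)]
        if n > 1 and np.any(off < 1):
            raise ValueError("all off-diagonal weights must be >= 1 deci-A")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def to_json(self) -> str:
        return json.dumps({
            "labels": [list(l) for l in self.labels],
            "weights": self.weights.tolist(),
            "source": self.source,
        })

    @classmethod
    def from_json(cls, text: str) -> "InteractionGraph":
        obj = json.loads(text)
        return cls([NodeLabel(*l) for l in obj["labels"]],
                   np.array(obj["weights"]), obj.get("source", ""))


def build_graph(triplets: Sequence[InteractionTriplet],
                source: str = "") -> InteractionGraph:
    """Build the complete IG for a list of triplets.

    Weights are ``round_half_up(distance_A) * 10`` deci-A, with rounded-zero
    (overlapping) pairs clamped to 1 deci-A so the edge survives.
    """
    if not triplets:
        raise EmptyGraphError("cannot build a graph from zero triplets")
    labels: list[NodeLabel] = []
    coords: list[np.ndarray] = []
    for t in triplets:
        for role, point in (("ligand", t.ligand_point),
                            ("protein", t.protein_point),
                            ("centre", t.centre_point)):
            labels.append(NodeLabel(t.itype, role))
            coords.append(point)
    xyz = np.vstack(coords)
    dist = squareform(pdist(xyz))
    weights = np.floor(dist + 0.5).astype(np.int64) * 10  # half-up, deci-A
    n = len(labels)
    off = ~np.eye(n, dtype=bool)
    weights[off & (weights == 0)] = 1
    np.fill_diagonal(weights, 0)
    return InteractionGraph(labels, weights, source)


def filter_polar(triplets: Iterable[InteractionTriplet]) -> list[InteractionTriplet]:
    """Drop hydrophobic (HYD) triplets; everything else passes, in order."""
    return [t for t in triplets if t.itype != "HYD"]


# ---------------------------------------------------------------------------
# IPA MOL2 dialect
# ---------------------------------------------------------------------------
#
# One ATOM record per pseudo-atom. The atom name encodes role and triplet
# index ("L3" = ligand IPA of triplet 3); the substructure name encodes
# "<itype>:<protein residue name>"; the substructure id carries the protein
# residue number; the charge column carries the ligand atom (or ring) id.

def write_ipa(triplets: Sequence[InteractionTriplet], mol_name: str = "IPA") -> str:
    """Serialise triplets as an IPA MOL2 document (lossless round trip)."""
    atoms: list[Atom] = []
    aid = 0
    for idx, t in enumerate(triplets, start=1):
        resname, resnum = t.protein_residue
        for role, point in (("ligand", t.ligand_point),
                            ("protein", t.protein_point),
                            ("centre", t.centre_point)):
            aid += 1
            atoms.append(Atom(
                atom_id=aid,
                name=f"{_ROLE_CODE[role]}{idx}",
                sybyl_type="Du",
                coords=point,
                partial_charge=float(t.ligand_atom_id),
                residue_name=f"{t.itype}:{resname}",
                residue_number=int(resnum),
            ))
    return write_mol2(MolecularStructure(atoms=atoms, bonds=[], mol_name=mol_name))


def read_ipa(source) -> list[InteractionTriplet]:
    """Parse an IPA MOL2 document back into triplets.

    A centre pseudo-atom that is not the midpoint of its two endpoints (to
    printed precision) triggers a warning and is recomputed.
    """
    structure = read_mol2(source)
    if not structure.atoms:
        return []
    groups: dict[int, dict[str, Atom]] = {}
    for atom in structure.atoms:
        code, idx_text = atom.name[0], atom.name[1:]
        if code not in _CODE_ROLE or not idx_text.isdigit():
            raise ValueError(f"unrecognised IPA atom name {atom.name!r}")
        groups.setdefault(int(idx_text), {})[_CODE_ROLE[code]] = atom

    triplets: list[InteractionTriplet] = []
    for idx in sorted(groups):
        grp = groups[idx]
        if set(grp) != set(ROLES):
            raise ValueError(f"IPA triplet {idx} is incomplete: has {sorted(grp)}")
        lig, prot, cen = grp["ligand"], grp["protein"], grp["centre"]
        itype, _, resname = lig.residue_name.partition(":")
        if itype not in ITYPES:
            raise ValueError(f"IPA triplet {idx}: unknown interaction type {itype!r}")
        mid = 0.5 * (lig.coords + prot.coords)
        if not np.allclose(cen.coords, mid, atol=5e-4):
            logger.warning("IPA triplet %d: centre is not the midpoint; recomputed", idx)
        triplets.append(InteractionTriplet.from_endpoints(
            itype, lig.coords, prot.coords,
            (resname, lig.residue_number), int(round(lig.partial_charge))))
    return triplets
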