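"""Geometric detection of protein-ligand interactions.

Seven interaction types are distinguished: hydrogen bonds split by direction
(HBA = protein accepts, HBD = protein donates), ionic contacts split by the
protein charge sign (ION_PPLUS / ION_PMINUS), aromatic stacking (ARO, pooling
face-to-face and edge-to-face), hydrophobic contacts (HYD) and metal
chelation (MET). Each detected interaction is emitted as a triplet of
interaction pseudo-atoms: one on the ligand atom (or ring centroid), one on
the protein atom, and one at the midpoint.

Hydrogen bonds and aromatic stacking carry both a distance and an angle
constraint; the remaining types are distance-only. The default thresholds are
configurable; they are conventional values, not published ones.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import chem_rules
from .structio import (
    Atom,
    ChemicalAnnotation,
    ComplexFrame,
    MolecularStructure,
    ring_angle_deg,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ITYPES",
    "GeometryConfig",
    "InteractionTriplet",
    "detect_interactions",
    "hydrophobic_environment",
    "count_by_type",
]

#: Canonical interaction-type order, used for node-label ordering everywhere.
ITYPES = ("HBA", "HBD", "ION_PPLUS", "ION_PMINUS", "ARO", "HYD", "MET")


@dataclass(frozen=True)
class GeometryConfig:
    """Distance/angle thresholds for interaction detection.

    ``hydrophobic_mode`` selects between the permissive definition (``hyd``,
    every C/S heavy-atom pair in range) and the stricter environment-aware
    one (``newhyd``, see :func:`hydrophobic_environment`).
    """

    hb_dist_max: float = 3.5
    hb_angle_min: float = 120.0
    ionic_dist_max: float = 4.0
    aro_dist_max: float = 4.0
    aro_ftf_angle_max: float = 30.0
    aro_etf_angle_min: float = 60.0
    hydrophobic_dist_max: float = 4.5
    metal_dist_max: float = 2.8
    hydrophobic_mode: str = "hyd"

    def __post_init__(self) -> None:
        for name in ("hb_dist_max", "ionic_dist_max", "aro_dist_max",
                     "hydrophobic_dist_max", "metal_dist_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hb_angle_min", "aro_ftf_angle_max", "aro_etf_angle_min"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must be in [0, 180]")
        if self.hydrophobic_mode not in ("hyd", "newhyd"):
            raise ValueError("hydrophobic_mode must be 'hyd' or 'newhyd'")

    @classmethod
    def reference(cls, **overrides) -> "GeometryConfig":
        """Pipeline configuration with the extended 5.0 A aromatic cutoff."""
        overrides.setdefault("aro_dist_max", 5.0)
        return cls(**overrides)


@dataclass(frozen=True, eq=False)
class InteractionTriplet:
    """One detected interaction as its three pseudo-atom positions."""

    itype: str
    ligand_point: np.ndarray
    protein_point: np.ndarray
    centre_point: np.ndarray
    protein_residue: tuple[str, int]
    ligand_atom_id: int

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")
        object.__setattr__(self, "ligand_point", np.asarray(self.ligand_point, float))
        object.__setattr__(self, "protein_point", np.asarray(self.protein_point, float))
        object.__setattr__(self, "centre_point", np.asarray(self.centre_point, float))
        mid = 0.5 * (self.ligand_point + self.protein_point)
        if not np.allclose(self.centre_point, mid, atol=1e-9):
            raise ValueError("centre_point must be the ligand/protein midpoint")

    @classmethod
    def from_endpoints(cls, itype, ligand_point, protein_point,
                       protein_residue, ligand_atom_id) -> "InteractionTriplet":
        lp = np.asarray(ligand_point, float)
        pp = np.asarray(protein_point, float)
        return cls(itype, lp, pp, 0.5 * (lp + pp), tuple(protein_residue),
                   int(ligand_atom_id))


def detect_interactions(
    frame: ComplexFrame,
    ann_p: ChemicalAnnotation,
    ann_l: ChemicalAnnotation,
    config: GeometryConfig | None = None,
) -> list[InteractionTriplet]:
    """Detect all interactions between the frame's protein and ligand.

    Exactly one triplet is emitted per qualifying atom (or ring) pair and
    direction. Empty annotations simply yield an empty list.
    """
    config = config or GeometryConfig()
    protein, ligand = frame.protein, frame.ligand
    out: list[InteractionTriplet] = []

    # --- hydrogen bonds -------------------------------------------------
    # HBA: ligand donates to a protein acceptor. HBD: protein donates.
    for l_id in sorted(ann_l.hbond_donor):
        for p_id in sorted(ann_p.hbond_acceptor):
            donor, acceptor = ligand.atom(l_id), protein.atom(p_id)
            if np.linalg.norm(donor.coords - acceptor.coords) > config.hb_dist_max:
                continue
            if not _hbond_angle_ok(donor, acceptor, ligand, ann_l, config):
                continue
            out.append(InteractionTriplet.from_endpoints(
                "HBA", donor.coords, acceptor.coords,
                (acceptor.residue_name, acceptor.residue_number), donor.atom_id))
    for p_id in sorted(ann_p.hbond_donor):
        for l_id in sorted(ann_l.hbond_acceptor):
            donor, acceptor = protein.atom(p_id), ligand.atom(l_id)
            if np.linalg.norm(donor.coords - acceptor.coords) > config.hb_dist_max:
                continue
            if not _hbond_angle_ok(donor, acceptor, protein, ann_p, config):
                continue
            out.append(InteractionTriplet.from_endpoints(
                "HBD", acceptor.coords, donor.coords,
                (donor.residue_name, donor.residue_number), acceptor.atom_id))

    # --- ionic ----------------------------------------------------------
    for itype, prot_ids, lig_ids in (
        ("ION_PPLUS", ann_p.cation, ann_l.anion),
        ("ION_PMINUS", ann_p.anion, ann_l.cation),
    ):
        for p_id in sorted(prot_ids):
            for l_id in sorted(lig_ids):
                pa, la = protein.atom(p_id), ligand.atom(l_id)
                if np.linalg.norm(pa.coords - la.coords) <= config.ionic_dist_max:
                    out.append(InteractionTriplet.from_endpoints(
                        itype, la.coords, pa.coords,
                        (pa.residue_name, pa.residue_number), la.atom_id))

    # --- aromatic stacking ---------------------------------------------
    for ri, lring in enumerate(ann_l.aromatic_rings):
        for pring in ann_p.aromatic_rings:
            d = float(np.linalg.norm(lring.centroid - pring.centroid))
            if d > config.aro_dist_max:
                continue
            angle = ring_angle_deg(lring.normal, pring.normal)
            if angle <= config.aro_ftf_angle_max or angle >= config.aro_etf_angle_min:
                ref = protein.atom(pring.member_ids[0])
                out.append(InteractionTriplet.from_endpoints(
                    "ARO", lring.centroid, pring.centroid,
                    (ref.residue_name, ref.residue_number), ri))

    # --- hydrophobic ----------------------------------------------------
    p_hyd = _hydrophobic_atoms(protein, ann_p, config)
    l_hyd = _hydrophobic_atoms(ligand, ann_l, config)
    if p_hyd and l_hyd:
        p_xyz = np.vstack([a.coords for a in p_hyd])
        l_xyz = np.vstack([a.coords for a in l_hyd])
        close = cdist(l_xyz, p_xyz) <= config.hydrophobic_dist_max
        for i, j in zip(*np.nonzero(close)):
            la, pa = l_hyd[i], p_hyd[j]
            out.append(InteractionTriplet.from_endpoints(
                "HYD", la.coords, pa.coords,
                (pa.residue_name, pa.residue_number), la.atom_id))

    # --- metal chelation (either side may hold the metal) ---------------
    for p_id in sorted(ann_p.metal):
        for l_id in sorted(ann_l.hbond_acceptor | ann_l.anion):
            pa, la = protein.atom(p_id), ligand.atom(l_id)
            if np.linalg.norm(pa.coords - la.coords) <= config.metal_dist_max:
                out.append(InteractionTriplet.from_endpoints(
                    "MET", la.coords, pa.coords,
                    (pa.residue_name, pa.residue_number), la.atom_id))
    for l_id in sorted(ann_l.metal):
        for p_id in sorted(ann_p.hbond_acceptor | ann_p.anion):
            pa, la = protein.atom(p_id), ligand.atom(l_id)
            if np.linalg.norm(pa.coords - la.coords) <= config.metal_dist_max:
                out.append(InteractionTriplet.from_endpoints(
                    "MET", la.coords, pa.coords,
                    (pa.residue_name, pa.residue_number), la.atom_id))

    return out


def _hbond_angle_ok(donor: Atom, acceptor: Atom, donor_struct: MolecularStructure,
                    donor_ann: ChemicalAnnotation, config: GeometryConfig) -> bool:
    """Donor-H...acceptor angle test with the best available hydrogen.

    Falls back to distance-only acceptance (with a warning) when the donor
    has no explicit hydrogen on record.
    """
    h_ids = donor_ann.donor_hydrogens.get(donor.atom_id, [])
    if not h_ids:
        logger.warning("donor atom %d has no explicit hydrogen; "
                       "distance-only hydrogen bond accepted", donor.atom_id)
        return True
    best = 0.0
    for h_id in h_ids:
        h = donor_struct.atom(h_id)
        v1 = donor.coords - h.coords
        v2 = acceptor.coords - h.coords
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        cosang = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
        best = max(best, math.degrees(math.acos(cosang)))
    return best >= config.hb_angle_min


def _hydrophobic_atoms(structure: MolecularStructure, ann: ChemicalAnnotation,
                       config: GeometryConfig) -> list[Atom]:
    atoms = [structure.atom(i) for i in sorted(ann.hydrophobic)]
    if config.hydrophobic_mode == "newhyd":
        atoms = [a for a in atoms if hydrophobic_environment(a, structure)]
    return atoms


def hydrophobic_environment(atom: Atom, structure: MolecularStructure) -> bool:
    """Stricter hydrophobic eligibility: no bonded N, O or charged neighbour.

    Only consulted in ``newhyd`` mode; the permissive ``hyd`` mode accepts
    every C/S heavy atom. An isolated atom passes vacuously.
    """
    for nb in structure.neighbours(atom.atom_id):
        if nb.is_hydrogen:
            continue
        if nb.element in ("N", "O") or chem_rules.is_charged_type(nb.sybyl_type):
            return False
    return True


def count_by_type(triplets: Iterable[InteractionTriplet]) -> dict[str, int]:
    """Interaction counts per type; every type key is present (0 default)."""
    counts = Counter(t.itype for t in triplets)
    return {t: counts.get(t, 0) for t in ITYPES}


def ipa_count(triplets: Sequence[InteractionTriplet]) -> int:
    """Total number of pseudo-atoms (three per interaction)."""
    return 3 * len(triplets)
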