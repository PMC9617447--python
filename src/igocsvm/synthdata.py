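"""Seeded generators for synthetic binding-mode ensembles and test fixtures.

A :class:`BindingModeTemplate` lists reference interactions with per-
interaction conservation probabilities; simulated "trajectory" frames include
each interaction with its probability, jitter the pseudo-atom endpoints with
isotropic Gaussian noise, and sprinkle spurious interactions near the
template. Decoy pose generators produce type-swapped, displaced and
interaction-subset variants, emulating non-agonist binding modes. Geometric
micro-fixtures build minimal protein/ligand structures at exact requested
geometry for interaction-detection tests.

All generators are driven by ``numpy.random.default_rng`` seeds and are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq

from .interactions import ITYPES, InteractionTriplet
from .structio import Atom, ComplexFrame, MolecularStructure

__all__ = [
    "TemplateInteraction",
    "BindingModeTemplate",
    "SimConfig",
    "default_template",
    "simulate_trajectory",
    "make_decoys",
    "geometry_fixture",
]

#: Spurious interactions are placed within this radius of the template
#: centroid so they pollute the same graph scale.
SPURIOUS_RADIUS = 8.0


@dataclass(frozen=True)
class TemplateInteraction:
    itype: str
    ligand_anchor: tuple[float, float, float]
    protein_anchor: tuple[float, float, float]
    residue: tuple[str, int]
    p: float

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise ValueError(f"unknown itype {self.itype!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("conservation probability must be in [0, 1]")
        la = np.asarray(self.ligand_anchor)
        pa = np.asarray(self.protein_anchor)
        if np.linalg.norm(la - pa) < 1.0:
            raise ValueError("anchors must be at least 1 A apart")


@dataclass(frozen=True)
class BindingModeTemplate:
    interactions: tuple[TemplateInteraction, ...]

    def __post_init__(self) -> None:
        if not any(t.p == 1.0 for t in self.interactions):
            raise ValueError("template needs at least one fully conserved anchor")

    def centroid(self) -> np.ndarray:
        pts = [np.asarray(t.ligand_anchor) for t in self.interactions]
        pts += [np.asarray(t.protein_anchor) for t in self.interactions]
        return np.mean(pts, axis=0)


@dataclass(frozen=True)
class SimConfig:
    n_frames: int = 500
    jitter_sigma: float = 0.5
    spurious_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0 or self.spurious_rate < 0:
            raise ValueError("jitter_sigma and spurious_rate must be >= 0")


def default_template() -> BindingModeTemplate:
    """Aminergic-receptor-like reference binding mode.

    A fully conserved ionic + hydrogen-bond anchor pair to an aspartate-like
    residue, strong hydrogen bonds to an asparagine-like and a serine-like
    residue, three hydrophobic contacts and one aromatic stacking, spread
    over roughly 10 A.
    """
    return BindingModeTemplate((
        TemplateInteraction("ION_PMINUS", (0.0, 0.0, 0.0), (2.8, 1.2, 0.0),
                            ("ASP113", 113), 1.0),
        TemplateInteraction("HBA", (0.4, -0.8, 0.6), (2.9, -1.6, 1.2),
                            ("ASP113", 113), 1.0),
        TemplateInteraction("HBD", (1.8, 1.5, 2.0), (3.2, 3.4, 3.6),
                            ("ASN312", 312), 0.9),
        TemplateInteraction("HBA", (2.2, 2.6, 1.4), (3.0, 4.9, 2.2),
                            ("ASN312", 312), 0.9),
        TemplateInteraction("HBA", (5.5, -1.0, 2.5), (8.0, -2.2, 3.4),
                            ("SER207", 207), 0.8),
        TemplateInteraction("HYD", (4.0, 0.5, 0.5), (6.5, 1.8, -0.8),
                            ("VAL114", 114), 0.8),
        TemplateInteraction("HYD", (5.2, 1.2, 2.8), (7.6, 2.6, 4.0),
                            ("PHE290", 290), 0.7),
        TemplateInteraction("HYD", (6.0, -0.5, 0.0), (8.4, -1.8, -1.2),
                            ("PHE289", 289), 0.6),
        TemplateInteraction("ARO", (5.0, 0.2, 1.5), (7.8, 1.0, 3.8),
                            ("PHE290", 290), 0.5),
    ))


def _jittered_triplet(rng: np.random.Generator, itype: str,
                      lig: np.ndarray, prot: np.ndarray,
                      residue: tuple[str, int], ligand_atom_id: int,
                      sigma: float) -> InteractionTriplet:
    lig = np.asarray(lig, float) + rng.normal(0.0, sigma, 3) if sigma > 0 \
        else np.asarray(lig, float)
    prot = np.asarray(prot, float) + rng.normal(0.0, sigma, 3) if sigma > 0 \
        else np.asarray(prot, float)
    return InteractionTriplet.from_endpoints(itype, lig, prot, residue,
                                             ligand_atom_id)


def simulate_frame(template: BindingModeTemplate, config: SimConfig,
                   rng: np.random.Generator) -> list[InteractionTriplet]:
    """One frame: Bernoulli inclusion, Gaussian jitter, Poisson spurious."""
    out: list[InteractionTriplet] = []
    for idx, t in enumerate(template.interactions):
        if t.p >= 1.0 or rng.random() < t.p:
            out.append(_jittered_triplet(
                rng, t.itype, np.asarray(t.ligand_anchor),
                np.asarray(t.protein_anchor), t.residue, idx,
                config.jitter_sigma))
    centre = template.centroid()
    n_spurious = int(rng.poisson(config.spurious_rate))
    for s in range(n_spurious):
        itype = ITYPES[int(rng.integers(len(ITYPES)))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        lig = centre + direction * rng.uniform(0.0, SPURIOUS_RADIUS)
        bond_dir = rng.normal(size=3)
        bond_dir /= np.linalg.norm(bond_dir)
        prot = lig + bond_dir * rng.uniform(2.5, 4.5)
        out.append(InteractionTriplet.from_endpoints(
            itype, lig, prot, ("SPU", 900 + s), 100 + s))
    return out


def simulate_trajectory(template: BindingModeTemplate,
                        config: SimConfig) -> list[list[InteractionTriplet]]:
    """Seeded frame series of triplet sets standing in for an MD ensemble."""
    rng = np.random.default_rng(config.seed)
    return [simulate_frame(template, config, rng)
            for _ in range(config.n_frames)]


def make_decoys(template: BindingModeTemplate, n: int, mode: str,
                config: SimConfig, displacement: float = 5.0,
                ) -> list[list[InteractionTriplet]]:
    """Seeded decoy poses emulating non-agonist binding modes.

    ``type_swap`` permutes interaction types among positions; ``displace``
    translates all protein-side anchors rigidly by ``displacement`` (>= 3 A);
    ``subset`` keeps at most half of the interactions, preferentially
    dropping the strongly conserved (p >= 0.8) ones.
    """
    if mode not in ("type_swap", "displace", "subset"):
        raise ValueError("mode must be 'type_swap', 'displace' or 'subset'")
    if mode == "displace" and displacement < 3.0:
        raise ValueError("displace mode requires displacement >= 3 A")
    rng = np.random.default_rng(config.seed)
    sigma = config.jitter_sigma
    out: list[list[InteractionTriplet]] = []
    base = template.interactions
    for _ in range(n):
        pose: list[InteractionTriplet] = []
        if mode == "type_swap":
            remap = _type_remap(rng)
            for idx, t in enumerate(base):
                pose.append(_jittered_triplet(
                    rng, remap[t.itype], np.asarray(t.ligand_anchor),
                    np.asarray(t.protein_anchor), t.residue, idx, sigma))
        elif mode == "displace":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = direction * displacement
            for idx, t in enumerate(base):
                pose.append(_jittered_triplet(
                    rng, t.itype, np.asarray(t.ligand_anchor),
                    np.asarray(t.protein_anchor) + shift, t.residue, idx,
                    sigma))
        else:  # subset
            order = sorted(range(len(base)), key=lambda i: base[i].p)
            keep = order[:max(1, len(base) // 2)]
            for idx in sorted(keep):
                t = base[idx]
                pose.append(_jittered_triplet(
                    rng, t.itype, np.asarray(t.ligand_anchor),
                    np.asarray(t.protein_anchor), t.residue, idx, sigma))
        out.append(pose)
    return out


def _type_remap(rng: np.random.Generator) -> dict[str, str]:
    """Random derangement of the interaction-type alphabet.

    Applied consistently across a pose, so every interaction changes type.
    A positional shuffle of the types would be weaker: with the geometry
    kept, any pair of positions whose type multiset survives the shuffle
    reproduces the exact (label-pair, length) feature of the original pose.
    The consistent remap leaves only accidental feature collisions.
    """
    # a single full cycle: fixed-point free AND free of 2-cycles, so no
    # unordered type pair {A, B} can map back onto itself
    order = rng.permutation(len(ITYPES))
    return {ITYPES[order[i]]: ITYPES[order[(i + 1) % len(order)]]
            for i in range(len(order))}


# ---------------------------------------------------------------------------
# Geometric micro-fixtures
# ---------------------------------------------------------------------------

def geometry_fixture(kind: str, distance: float, angle: float = 180.0,
                     ligand_neighbour: str | None = None) -> ComplexFrame:
    """Minimal protein/ligand pair with one feature pair at exact geometry.

    ``kind`` selects the arrangement: ``hbond`` (protein acceptor O, ligand
    donor N-H; ``angle`` is the donor-H...acceptor angle), ``ionic``
    (carboxylate / ammonium), ``aromatic`` (two 6-rings, centroids
    ``distance`` apart, planes tilted by ``angle``), ``hydrophobic`` (C...C;
    ``ligand_neighbour`` optionally bonds an atom of the given SYBYL type to
    the ligand carbon), ``metal`` (Zn ... carbonyl O).
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    if kind == "hbond":
        return _hbond_fixture(distance, angle)
    if kind == "ionic":
        protein = MolecularStructure(
            atoms=[Atom(1, "C", "C.2", (distance + 1.3, 0.0, 0.0),
                        residue_name="ASP", residue_number=1),
                   Atom(2, "OD1", "O.co2", (distance, 0.0, 0.0),
                        residue_name="ASP", residue_number=1),
                   Atom(3, "OD2", "O.co2", (distance + 1.9, 1.1, 0.0),
                        residue_name="ASP", residue_number=1)],
            bonds=[(1, 2, "ar"), (1, 3, "ar")], mol_name="prot")
        ligand = MolecularStructure(
            atoms=[Atom(1, "N", "N.4", (0.0, 0.0, 0.0))], mol_name="lig")
        return ComplexFrame(protein, ligand)
    if kind == "aromatic":
        return _aromatic_fixture(distance, angle)
    if kind == "hydrophobic":
        lig_atoms = [Atom(1, "C1", "C.3", (0.0, 0.0, 0.0))]
        lig_bonds = []
        if ligand_neighbour is not None:
            lig_atoms.append(Atom(2, "X1", ligand_neighbour, (0.0, 1.5, 0.0)))
            lig_bonds.append((1, 2, "1"))
        protein = MolecularStructure(
            atoms=[Atom(1, "CB", "C.3", (distance, 0.0, 0.0),
                        residue_name="VAL", residue_number=1)], mol_name="prot")
        return ComplexFrame(protein,
                            MolecularStructure(lig_atoms, lig_bonds, "lig"))
    if kind == "metal":
        protein = MolecularStructure(
            atoms=[Atom(1, "ZN", "Zn", (distance, 0.0, 0.0),
                        residue_name="ZN", residue_number=1)], mol_name="prot")
        ligand = MolecularStructure(
            atoms=[Atom(1, "O1", "O.2", (0.0, 0.0, 0.0)),
                   Atom(2, "C1", "C.2", (-1.2, 0.0, 0.0))],
            bonds=[(1, 2, "2")], mol_name="lig")
        return ComplexFrame(protein, ligand)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _hbond_fixture(distance: float, angle: float) -> ComplexFrame:
    """Donor N at (d,0,0), acceptor O at origin, H placed at 1.0 A from N so
    that the N-H...O angle equals ``angle`` (degrees)."""
    if not 0.0 < angle <= 180.0:
        raise ValueError("hbond angle must be in (0, 180]")
    n_pos = np.array([distance, 0.0, 0.0])
    o_pos = np.zeros(3)

    def angle_at_h(tilt: float) -> float:
        h = n_pos + np.array([-math.cos(tilt), math.sin(tilt), 0.0])
        v1, v2 = n_pos - h, o_pos - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))

    if distance <= 1.0:
        raise ValueError("donor-acceptor distance must exceed the 1 A N-H bond")
    lo, hi = 1e-9, math.pi - 1e-9
    f_lo, f_hi = angle_at_h(lo) - angle, angle_at_h(hi) - angle
    if f_lo * f_hi > 0:
        raise ValueError(f"cannot realise hbond angle {angle} at distance {distance}")
    tilt = brentq(lambda t: angle_at_h(t) - angle, lo, hi)
    h_pos = n_pos + np.array([-math.cos(tilt), math.sin(tilt), 0.0])

    protein = MolecularStructure(
        atoms=[Atom(1, "O", "O.2", o_pos, residue_name="SER", residue_number=1),
               Atom(2, "C", "C.2", (-1.2, 0.0, 0.0),
                    residue_name="SER", residue_number=1)],
        bonds=[(1, 2, "2")], mol_name="prot")
    ligand = MolecularStructure(
        atoms=[Atom(1, "N1", "N.3", n_pos),
               Atom(2, "H1", "H", h_pos),
               Atom(3, "C1", "C.3", n_pos + np.array([1.45, 0.0, 0.0]))],
        bonds=[(1, 2, "1"), (1, 3, "1")], mol_name="lig")
    return ComplexFrame(protein, ligand)


def _aromatic_fixture(distance: float, angle: float) -> ComplexFrame:
    """Two benzene-like rings: ligand ring in the z=0 plane at the origin,
    protein ring at (0,0,distance) tilted by ``angle`` degrees."""
    theta = np.linspace(0.0, 2.0 * math.pi, 7)[:-1]
    ring = np.column_stack([1.39 * np.cos(theta), 1.39 * np.sin(theta),
                            np.zeros(6)])
    tilt = math.radians(angle)
    rot = np.array([[1.0, 0.0, 0.0],
                    [0.0, math.cos(tilt), -math.sin(tilt)],
                    [0.0, math.sin(tilt), math.cos(tilt)]])
    prot_ring = ring @ rot.T + np.array([0.0, 0.0, distance])

    def make(coords: np.ndarray, resname: str) -> MolecularStructure:
        atoms = [Atom(i + 1, f"C{i + 1}", "C.ar", coords[i],
                      residue_name=resname, residue_number=1)
                 for i in range(6)]
        bonds = [(i + 1, (i + 1) % 6 + 1, "ar") for i in range(6)]
        return MolecularStructure(atoms, bonds, resname)

    return ComplexFrame(make(prot_ring, "PHE"), make(ring, "LIG"))
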