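"""Binding-site definition, pairwise RMSD, and conformation clustering.

Frames are assumed pre-aligned: the RMSD is the plain coordinate formula
sqrt(sum((X_i - Y_i)^2) / N) with no superposition term (an optional Kabsch
pre-alignment flag exists but defaults off). Clustering operates on the
precomputed RMSD matrix, either with average-linkage hierarchical clustering
or with a deterministic PAM-style k-medoids (BUILD initialisation + swap
refinement, implemented here because no seeded k-medoids is available in the
pinned dependency set). Representative structures are cluster medoids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .structio import ComplexFrame

logger = logging.getLogger(__name__)

__all__ = [
    "BindingSiteDefinition",
    "ClusterAssignment",
    "binding_site",
    "shared_binding_site",
    "pairwise_rmsd",
    "cluster",
    "cluster_quality",
    "choose_k",
]


@dataclass
class BindingSiteDefinition:
    """Heavy-atom (system-specific) or residue-level (shared) site selection."""

    scope: str  # "system_specific" | "shared"
    atom_selection: list[tuple[int, str, str]] = field(default_factory=list)
    residue_selection: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scope not in ("system_specific", "shared"):
            raise ValueError("scope must be 'system_specific' or 'shared'")
        if self.scope == "system_specific" and not self.atom_selection:
            raise ValueError("system-specific definition must select atoms")
        if self.scope == "shared" and not self.residue_selection:
            raise ValueError("shared definition must select residues")


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    medoid_ids: list[int]
    quality: tuple[float, float, float] | None = None  # (silhouette, dunn, db)


def binding_site(frames: Sequence[ComplexFrame], cutoff: float = 4.5,
                 min_fraction: float = 0.10) -> BindingSiteDefinition:
    """System-specific binding site over a frame series.

    A protein heavy atom (keyed by residue number, residue name, atom name)
    is selected when it lies strictly closer than ``cutoff`` to any ligand
    heavy atom in at least ``min_fraction`` of the frames.
    """
    if not frames:
        raise ValueError("binding_site requires at least one frame")
    hits: dict[tuple[int, str, str], int] = {}
    for frame in frames:
        lig = np.vstack([a.coords for a in frame.ligand.heavy_atoms()])
        for atom in frame.protein.heavy_atoms():
            d = np.linalg.norm(lig - atom.coords, axis=1).min()
            if d < cutoff:
                key = (atom.residue_number, atom.residue_name, atom.name)
                hits[key] = hits.get(key, 0) + 1
    n = len(frames)
    selection = sorted(k for k, c in hits.items() if c / n >= min_fraction)
    if not selection:
        raise ValueError("binding site selection is empty")
    return BindingSiteDefinition("system_specific", atom_selection=selection)


def shared_binding_site(definitions: Iterable[BindingSiteDefinition]) -> BindingSiteDefinition:
    """Residue-level union of several system-specific definitions."""
    residues = set()
    for d in definitions:
        for resnum, resname, _ in d.atom_selection:
            residues.add((resnum, resname))
    if not residues:
        raise ValueError("shared binding site is empty")
    return BindingSiteDefinition("shared", residue_selection=sorted(residues))


def _resolve(frame: ComplexFrame, selection: BindingSiteDefinition) -> np.ndarray:
    by_key = {(a.residue_number, a.residue_name, a.name): a
              for a in frame.protein.heavy_atoms()}
    coords = []
    if selection.scope == "system_specific":
        for key in selection.atom_selection:
            if key not in by_key:
                raise ValueError(f"frame {frame.frame_index}: atom {key} not found")
            coords.append(by_key[key].coords)
    else:
        wanted = set(selection.residue_selection)
        for a in frame.protein.heavy_atoms():
            if (a.residue_number, a.residue_name) in wanted:
                coords.append(a.coords)
    return np.vstack(coords)


def pairwise_rmsd(frames: Sequence[ComplexFrame],
                  selection: BindingSiteDefinition,
                  superpose: bool = False) -> np.ndarray:
    """Pairwise binding-site RMSD matrix over a frame series.

    No superposition by default (frames are assumed pre-aligned); pass
    ``superpose=True`` for an optional Kabsch fit of each pair.
    """
    stacks = [_resolve(f, selection) for f in frames]
    n_atoms = {s.shape[0] for s in stacks}
    if len(n_atoms) != 1:
        raise ValueError(f"inconsistent selection sizes across frames: {n_atoms}")
    xyz = np.stack(stacks)  # (F, N, 3)
    f = xyz.shape[0]
    out = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            a, b = xyz[i], xyz[j]
            if superpose:
                b = _kabsch_fit(b, a)
            out[i, j] = out[j, i] = float(
                np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return out


def _kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    m, t = mobile - mc, target - tc
    u, _, vt = np.linalg.svd(m.T @ t)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = (u @ d @ vt)
    return m @ rot + tc


def _medoid_of(matrix: np.ndarray, members: np.ndarray) -> int:
    sub = matrix[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.sum(axis=1)))])


def cluster(matrix: np.ndarray, method: str = "kmedoids", k: int = 2,
            seed: int = 0, max_iter: int = 300) -> ClusterAssignment:
    """Cluster a precomputed distance matrix into k groups.

    ``hierarchical_average`` uses scipy's average linkage; ``kmedoids`` is a
    deterministic PAM (BUILD + swap; the seed only breaks exact ties).
    Medoids minimise the summed within-cluster distance.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of frames ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if method == "hierarchical_average":
        condensed = squareform(matrix, checks=False)
        labels = fcluster(linkage(condensed, method="average"),
                          t=k, criterion="maxclust") - 1
    elif method == "kmedoids":
        labels = _pam(matrix, k, seed, max_iter)
    else:
        raise ValueError("method must be 'hierarchical_average' or 'kmedoids'")

    labels = _canonical_labels(labels)
    if len(np.unique(labels)) < k:
        warnings.warn(f"degenerate distance matrix: only "
                      f"{len(np.unique(labels))} distinct clusters for k={k}; "
                      "splitting arbitrarily")
        labels = labels.copy()
        for extra, idx in enumerate(range(n - (k - len(np.unique(labels))), n)):
            labels[idx] = labels.max() + 1
        labels = _canonical_labels(labels)
    medoids = [_medoid_of(matrix, np.nonzero(labels == c)[0])
               for c in range(labels.max() + 1)]
    return ClusterAssignment(labels, int(labels.max() + 1), medoids)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _pam(matrix: np.ndarray, k: int, seed: int, max_iter: int) -> np.ndarray:
    n = matrix.shape[0]
    # BUILD: greedily add the medoid giving the largest cost reduction
    medoids = [int(np.argmin(matrix.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_idx = -np.inf, None
        current = matrix[:, medoids].min(axis=1)
        for cand in range(n):
            if cand in medoids:
                continue
            gain = float(np.sum(np.maximum(current - matrix[:, cand], 0.0)))
            if gain > best_gain:
                best_gain, best_idx = gain, cand
        medoids.append(int(best_idx))
    # SWAP refinement
    for _ in range(max_iter):
        assign = np.argmin(matrix[:, medoids], axis=1)
        cost = matrix[np.arange(n), np.array(medoids)[assign]].sum()
        improved = False
        for mi in range(k):
            members = np.nonzero(assign == mi)[0]
            if members.size == 0:
                continue
            for cand in members:
                if cand == medoids[mi]:
                    continue
                trial = list(medoids)
                trial[mi] = int(cand)
                trial_cost = matrix[:, trial].min(axis=1).sum()
                if trial_cost + 1e-12 < cost:
                    medoids, cost, improved = trial, trial_cost, True
        if not improved:
            break
    return np.argmin(matrix[:, medoids], axis=1)


def cluster_quality(matrix: np.ndarray,
                    labels: np.ndarray) -> tuple[float, float, float]:
    """(silhouette, Dunn index, Davies-Bouldin) from a distance matrix.

    Davies-Bouldin uses cluster medoids as centres since only pairwise
    distances are available. All clusters being singletons is an error
    (silhouette undefined).
    """
    matrix = np.asarray(matrix, float)
    labels = np.asarray(labels)
    clusters = [np.nonzero(labels == c)[0] for c in np.unique(labels)]
    if len(clusters) < 2:
        raise ValueError("quality indices require at least 2 clusters")
    if all(len(c) == 1 for c in clusters):
        raise ValueError("silhouette undefined for singleton-only clusterings")
    sil = float(silhouette_score(matrix, labels, metric="precomputed"))

    # Dunn: min inter-cluster distance / max intra-cluster diameter
    diameters = [float(matrix[np.ix_(c, c)].max()) for c in clusters]
    min_inter = min(
        float(matrix[np.ix_(ci, cj)].min())
        for a, ci in enumerate(clusters) for cj in clusters[a + 1:])
    max_diam = max(diameters)
    dunn = float("inf") if max_diam == 0 else min_inter / max_diam

    # Davies-Bouldin with medoid centres
    medoids = [_medoid_of(matrix, c) for c in clusters]
    scatter = [float(matrix[m, c].mean()) for m, c in zip(medoids, clusters)]
    ratios = []
    for i in range(len(clusters)):
        worst = 0.0
        for j in range(len(clusters)):
            if i == j:
                continue
            sep = matrix[medoids[i], medoids[j]]
            worst = max(worst, (scatter[i] + scatter[j]) / sep if sep > 0
                        else float("inf"))
        ratios.append(worst)
    db = float(np.mean(ratios))
    return sil, dunn, db


def choose_k(matrix: np.ndarray, method: str = "kmedoids",
             k_range: Iterable[int] = range(2, 11), seed: int = 0) -> int:
    """Pick k by majority vote of silhouette (max), Dunn (max), DB (min).

    Ties — including three-way disagreement — resolve toward the smallest
    voted k.
    """
    ks, sils, dunns, dbs = [], [], [], []
    for k in k_range:
        assignment = cluster(matrix, method, k, seed)
        try:
            sil, dunn, db = cluster_quality(matrix, assignment.labels)
        except ValueError:
            continue
        ks.append(k)
        sils.append(sil)
        dunns.append(dunn)
        dbs.append(db)
    if not ks:
        raise ValueError("no valid k in range")
    votes = [ks[int(np.argmax(sils))], ks[int(np.argmax(dunns))],
             ks[int(np.argmin(dbs))]]
    counts = {k: votes.count(k) for k in set(votes)}
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best)
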