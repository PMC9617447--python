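"""Screening pipeline: pose scoring, molecule decisions, metrics, IFP baseline.

A molecule is classified as an agonist when at least one of its docking
poses (all stereoisomers pooled; in ensemble mode, all receptor structures
pooled) is an inlier under the one-class model. Performance is summarised by
precision, recall and F1 over the agonist class; antagonists and inactives
both count as non-agonists.

The interaction-fingerprint (IFP) baseline encodes each pose as a binary
(residue x interaction type) bit vector compared by Tanimoto similarity,
with an exhaustive F1-maximising threshold sweep standing in for the
model-free rescoring methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .interactions import ITYPES, InteractionTriplet

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "BinaryIFP",
    "classify_molecule",
    "evaluate",
    "compute_ifp",
    "average_ifp",
    "ifp_tanimoto",
    "optimal_threshold",
    "round_table",
]

POSITIVE_CLASS = "agonist"
NEGATIVE_CLASSES = ("antagonist", "inactive")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    n_selected: int
    n_total: int

    @classmethod
    def from_confusion(cls, c: ConfusionCounts) -> "MetricsReport":
        precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
        recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) else 0.0)
        return cls(precision, recall, f1, c.TP + c.FP,
                   c.TP + c.FP + c.FN + c.TN)


def round_table(value: float, decimals: int = 2) -> float:
    """Half-up rounding used for report tables (0.945 -> 0.95)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def classify_molecule(pose_predictions: Iterable[bool]) -> str:
    """Agonist iff at least one pose is an inlier.

    Pose predictions from every stereoisomer (and, in ensemble mode, every
    representative receptor structure) are pooled before this rule applies.
    """
    preds = list(pose_predictions)
    if not preds:
        warnings.warn("molecule has no scored poses; classified as non_agonist")
        return "non_agonist"
    return POSITIVE_CLASS if any(preds) else "non_agonist"


def evaluate(decisions: Mapping[str, str], labels: Mapping[str, str],
             positive_class: str = POSITIVE_CLASS,
             ) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and metrics for a set of molecule-level decisions.

    ``decisions`` maps molecule id to the predicted class ("agonist" or
    anything else = non-agonist); ``labels`` maps molecule id to the true
    class, where both "antagonist" and "inactive" count as negatives.
    """
    missing = sorted(set(decisions) - set(labels))
    if missing:
        raise KeyError(f"unlabeled molecules: {missing}")
    tp = fp = fn = tn = 0
    for mol, decided in decisions.items():
        truth_pos = labels[mol] == positive_class
        decided_pos = decided == positive_class
        if decided_pos and truth_pos:
            tp += 1
        elif decided_pos:
            fp += 1
        elif truth_pos:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp, fp, fn, tn)
    return counts, MetricsReport.from_confusion(counts)


# ---------------------------------------------------------------------------
# Binary interaction fingerprints
# ---------------------------------------------------------------------------

@dataclass
class BinaryIFP:
    """Bit vector over (binding-site residue x interaction type)."""

    bits: np.ndarray
    universe: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        expected = (len(self.universe), len(ITYPES))
        if self.bits.shape != expected:
            raise ValueError(f"bits shape {self.bits.shape} != {expected}")


def compute_ifp(triplets: Iterable[InteractionTriplet],
                residue_universe: Sequence[tuple[str, int]]) -> BinaryIFP:
    """Binary IFP of one pose: bit (r, t) set iff a type-t triplet touches r."""
    universe = tuple(tuple(r) for r in residue_universe)
    index = {r: i for i, r in enumerate(universe)}
    bits = np.zeros((len(universe), len(ITYPES)), dtype=bool)
    for t in triplets:
        key = tuple(t.protein_residue)
        if key not in index:
            raise ValueError(f"residue {key} outside the IFP universe")
        bits[index[key], ITYPES.index(t.itype)] = True
    return BinaryIFP(bits, universe)


def average_ifp(ifps: Sequence[BinaryIFP],
                crystal: BinaryIFP | None = None,
                min_fraction: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Per-bit frequency over an ensemble, plus the display mask.

    The mask shows bits present in at least ``min_fraction`` of the frames or
    present in the supplied crystallographic IFP; it affects reporting only.
    """
    if not ifps:
        raise ValueError("average_ifp requires at least one IFP")
    universe = ifps[0].universe
    for ifp in ifps:
        if ifp.universe != universe:
            raise ValueError("IFP universe mismatch")
    freq = np.mean([ifp.bits for ifp in ifps], axis=0)
    mask = freq >= min_fraction
    if crystal is not None:
        if crystal.universe != universe:
            raise ValueError("crystal IFP universe mismatch")
        mask = mask | crystal.bits
    return freq, mask


def ifp_tanimoto(a: BinaryIFP, b: BinaryIFP) -> float:
    """Tanimoto similarity |a & b| / |a | b|; 0 (with warning) if both empty."""
    if a.universe != b.universe:
        raise ValueError("IFP universe mismatch")
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        warnings.warn("both IFPs are empty; Tanimoto defined as 0")
        return 0.0
    return float(np.sum(a.bits & b.bits) / union)


# ---------------------------------------------------------------------------
# Threshold sweep for score-based baselines
# ---------------------------------------------------------------------------

def optimal_threshold(scores: Mapping[str, float], labels: Mapping[str, str],
                      positive_class: str = POSITIVE_CLASS,
                      ) -> tuple[float, MetricsReport]:
    """F1-maximising decision threshold over per-molecule scores.

    A molecule is selected when score >= threshold. Candidates are the
    minimum score (select-all) plus the midpoints of consecutive sorted
    unique scores; ties resolve to the lowest threshold.
    """
    if not scores:
        raise ValueError("no scores supplied")
    uniq = np.unique(list(scores.values()))
    if uniq.size == 1:
        warnings.warn("all scores equal; threshold degenerate")
        candidates = [float(uniq[0])]
    else:
        candidates = [float(uniq[0])] + [float(0.5 * (a + b))
                                         for a, b in zip(uniq[:-1], uniq[1:])]
    best_t, best_report = None, None
    for t in candidates:
        decisions = {mol: (positive_class if s >= t else "non_agonist")
                     for mol, s in scores.items()}
        _, report = evaluate(decisions, labels, positive_class)
        if best_report is None or report.f1 > best_report.f1 + 1e-12:
            best_t, best_report = t, report
    return best_t, best_report
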