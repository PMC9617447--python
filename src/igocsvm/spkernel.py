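"""Shortest-path graph kernel over interaction graphs.

A graph is summarised as a sparse fingerprint counting, for every unordered
node pair, the feature (label_a, label_b, shortest-path length). Rounded
weights and the 1 deci-A overlap edges can break the triangle inequality, so
true all-pairs shortest paths are computed — direct edges are never assumed
shortest. Two fingerprints are compared by dot product (non-normalized, "nn")
or cosine (normalized).

The feature set ("vocabulary") is learned from a training collection. When a
query graph is scored against the training set the vocabulary is extended
temporarily: novel query features contribute to the query norm in normalized
mode but are ignored entirely in nn mode, and the stored vocabulary is left
unchanged.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .iggraph import InteractionGraph, NodeLabel

logger = logging.getLogger(__name__)

__all__ = [
    "PathFeature",
    "PathFingerprint",
    "Vocabulary",
    "GramMatrix",
    "shortest_path_lengths",
    "fingerprint",
    "similarity",
    "gram",
    "cross",
]


class PathFeature(NamedTuple):
    """Canonically ordered label pair plus shortest-path length (deci-A)."""

    label_a: NodeLabel
    label_b: NodeLabel
    length: int


def make_feature(la: NodeLabel, lb: NodeLabel, length: int) -> PathFeature:
    """Build a feature with the label pair in canonical (fixed total) order."""
    if lb.sort_key() < la.sort_key():
        la, lb = lb, la
    return PathFeature(la, lb, int(length))


#: A fingerprint is a sparse mapping PathFeature -> count.
PathFingerprint = Counter


def shortest_path_lengths(graph: InteractionGraph) -> np.ndarray:
    """Exact all-pairs shortest paths of the weighted graph, as integers."""
    n = graph.n_nodes
    if n <= 1:
        return np.zeros((n, n), dtype=np.int64)
    dist = _csgraph_shortest_path(graph.weights.astype(float),
                                  method="D", directed=False)
    return np.rint(dist).astype(np.int64)


def fingerprint(graph: InteractionGraph) -> PathFingerprint:
    """Fingerprint a graph: one feature per unordered node pair.

    The total count equals n(n-1)/2 for an n-node graph; node self-pairs are
    excluded.
    """
    sp = shortest_path_lengths(graph)
    fp: PathFingerprint = Counter()
    labels = graph.labels
    n = graph.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            fp[make_feature(labels[i], labels[j], sp[i, j])] += 1
    return fp


def _norm(fp: PathFingerprint) -> float:
    return float(np.sqrt(sum(c * c for c in fp.values())))


def similarity(fp1: PathFingerprint, fp2: PathFingerprint,
               mode: str = "normalized") -> float:
    """Kernel value between two fingerprints.

    ``nn`` is the plain dot product of counts; ``normalized`` is the cosine,
    defined as 0 (with a warning) when either fingerprint has zero norm.
    """
    if mode not in ("normalized", "nn"):
        raise ValueError("mode must be 'normalized' or 'nn'")
    small, large = (fp1, fp2) if len(fp1) <= len(fp2) else (fp2, fp1)
    dot = float(sum(c * large[f] for f, c in small.items()))
    if mode == "nn":
        return dot
    n1, n2 = _norm(fp1), _norm(fp2)
    if n1 == 0.0 or n2 == 0.0:
        logger.warning("zero-norm fingerprint in normalized similarity; returning 0")
        return 0.0
    return dot / (n1 * n2)


@dataclass
class Vocabulary:
    """Learned, deterministically ordered feature list with an index."""

    features: list[PathFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {f: i for i, f in enumerate(self.features)}
        if len(self._index) != len(self.features):
            raise ValueError("vocabulary contains duplicate features")

    @classmethod
    def fit(cls, fps: Iterable[PathFingerprint]) -> "Vocabulary":
        seen = set()
        for fp in fps:
            seen.update(fp.keys())
        ordered = sorted(seen, key=lambda f: (f.label_a.sort_key(),
                                              f.label_b.sort_key(), f.length))
        return cls(ordered)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature: PathFeature) -> bool:
        return feature in self._index

    def vector(self, fp: PathFingerprint) -> np.ndarray:
        """Dense count vector over the vocabulary (unseen features dropped)."""
        v = np.zeros(len(self.features), dtype=float)
        for f, c in fp.items():
            idx = self._index.get(f)
            if idx is not None:
                v[idx] = c
        return v

    def matrix(self, fps: Sequence[PathFingerprint]) -> np.ndarray:
        return np.vstack([self.vector(fp) for fp in fps]) if fps else \
            np.zeros((0, len(self.features)))

    def to_json(self) -> str:
        return json.dumps([[list(f.label_a), list(f.label_b), f.length]
                           for f in self.features])

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls([PathFeature(NodeLabel(*a), NodeLabel(*b), int(length))
                    for a, b, length in json.loads(text)])


@dataclass
class GramMatrix:
    """Symmetric kernel matrix over a fingerprint collection."""

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("Gram matrix must be square")
        if self.mode not in ("normalized", "nn"):
            raise ValueError("mode must be 'normalized' or 'nn'")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def gram(train_fps: Sequence[PathFingerprint], mode: str = "normalized",
         vocabulary: Vocabulary | None = None) -> GramMatrix:
    """Pairwise kernel matrix of a training collection."""
    vocab = vocabulary or Vocabulary.fit(train_fps)
    m = vocab.matrix(train_fps)
    values = m @ m.T
    if mode == "normalized":
        norms = np.sqrt(np.diag(values))
        safe = np.where(norms == 0, 1.0, norms)
        values = values / np.outer(safe, safe)
        values[norms == 0, :] = 0.0
        values[:, norms == 0] = 0.0
    return GramMatrix(values, mode)


def cross(train_fps: Sequence[PathFingerprint], query_fp: PathFingerprint,
          mode: str = "normalized",
          vocabulary: Vocabulary | None = None) -> np.ndarray:
    """Kernel vector of a query fingerprint against the training collection.

    Dot products run over the fitted vocabulary only. In normalized mode the
    query norm is taken over the temporarily extended vocabulary — i.e. novel
    query features deflate the cosine — while nn mode ignores them entirely.
    The supplied vocabulary object is never mutated.
    """
    vocab = vocabulary or Vocabulary.fit(train_fps)
    m = vocab.matrix(train_fps)
    q = vocab.vector(query_fp)
    dots = m @ q
    if mode == "nn":
        return dots
    # full query norm, including features outside the stored vocabulary
    q_norm = _norm(query_fp)
    t_norms = np.linalg.norm(m, axis=1)
    out = np.zeros_like(dots)
    ok = (t_norms > 0) & (q_norm > 0)
    if q_norm == 0:
        logger.warning("zero-norm query fingerprint; cross similarities set to 0")
    out[ok] = dots[ok] / (t_norms[ok] * q_norm)
    return out
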