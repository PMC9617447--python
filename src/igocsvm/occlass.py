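"""One-class SVM training on a single reference ensemble.

The training set is the collection of interaction-graph fingerprints from a
reference trajectory. Two heuristics set the nu hyperparameter without an
external validation set, both starting from the per-instance average kernel
similarity to the K nearest neighbours (K = 3% of the training size):

* QMS2 — sort the KNN-similarity profile ascending, find the first knee of
  the rank-vs-similarity curve with the kneedle construction, discard the
  instances below the knee, and train with nu = 0.01.
* MAD — keep every instance and set nu to the fraction of instances whose
  similarity deviates from the median by more than 3 x the (raw, unscaled)
  median absolute deviation.

The nu-OCSVM dual (min 1/2 a'Ka, 0 <= a_i <= 1/(nu n), sum a = 1) is solved
through scikit-learn's precomputed-kernel ``OneClassSVM``; the libsvm
coefficients are rescaled so the stored model satisfies sum(alpha) = 1.
Signed decision scores follow the convention: negative = outlier,
non-negative = inlier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import OneClassSVM

from . import spkernel
from .iggraph import InteractionGraph
from .spkernel import GramMatrix, PathFingerprint, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityProfile",
    "TrainingSelection",
    "OneClassModel",
    "knn_profile",
    "kneedle_knee",
    "qms2_select",
    "mad_nu",
    "train_ocsvm",
    "fit_model",
    "score_graph",
    "predict",
]

#: Scores above -SCORE_EPS count as inliers when measuring the nu-property;
#: margin support vectors land at 0 up to solver noise.
SCORE_EPS = 1e-7


@dataclass
class SimilarityProfile:
    """Average similarity of each training instance to its K neighbours."""

    s: np.ndarray
    K: int
    N: int

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (self.N,):
            raise ValueError("profile length must equal N")


@dataclass
class TrainingSelection:
    """Outcome of a nu heuristic: retained instances plus the nu value."""

    retained_indices: np.ndarray
    nu: float
    method: str

    def __post_init__(self) -> None:
        self.retained_indices = np.asarray(self.retained_indices, dtype=int)
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must lie in (0, 1]")


def knn_profile(gram: GramMatrix | np.ndarray) -> SimilarityProfile:
    """KNN similarity profile of a training Gram matrix.

    K is 3% of the training size (at least 1); the self-similarity diagonal
    is excluded from each row's neighbour pool.
    """
    K_mat = gram.values if isinstance(gram, GramMatrix) else np.asarray(gram, float)
    n = K_mat.shape[0]
    if n < 2:
        raise ValueError("KNN profile requires at least 2 training instances")
    k = max(1, int(round(0.03 * n)))
    off = K_mat[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    top = np.sort(off, axis=1)[:, -k:]
    return SimilarityProfile(top.mean(axis=1), K=k, N=n)


def kneedle_knee(values: Sequence[float], sensitivity: float = 1.0) -> int | None:
    """First knee of an ascending concave curve, per the kneedle construction.

    Both axes are min-max normalised, the difference curve d = y - x is
    formed, and the first local maximum of d whose height survives the
    sensitivity-scaled decay threshold is returned as the knee index.
    Returns None for flat, too-short, or knee-free inputs.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3 or v[-1] == v[0]:
        return None
    if np.any(np.diff(v) < 0):
        raise ValueError("kneedle_knee expects an ascending-sorted vector")
    x = np.arange(n) / (n - 1)
    y = (v - v[0]) / (v[-1] - v[0])
    d = y - x
    maxima = [i for i in range(1, n - 1)
              if d[i] > d[i - 1] and d[i] >= d[i + 1]]
    if not maxima:
        return None
    step = sensitivity / (n - 1)  # mean x-spacing times sensitivity
    for pos, lmx in enumerate(maxima):
        threshold = d[lmx] - step
        stop = maxima[pos + 1] if pos + 1 < len(maxima) else n
        for j in range(lmx + 1, stop):
            if d[j] < threshold:
                return lmx
    return None


def qms2_select(profile: SimilarityProfile,
                sensitivity: float = 1.0) -> TrainingSelection:
    """QMS2: drop low-similarity instances below the first kneedle knee.

    The discard rule is value-based (every instance whose similarity is
    strictly below the knee value), making the retained set invariant under
    permutations of the training order. Without a knee everything is kept.
    In both cases nu = 0.01.
    """
    order = np.argsort(profile.s, kind="stable")
    sorted_s = profile.s[order]
    knee = kneedle_knee(sorted_s, sensitivity)
    if knee is None:
        retained = np.arange(profile.N)
    else:
        retained = np.nonzero(profile.s >= sorted_s[knee])[0]
        if retained.size == 0:  # defensive; cannot happen for a valid knee
            retained = np.arange(profile.N)
    return TrainingSelection(retained, nu=0.01, method="qms2")


def mad_nu(profile: SimilarityProfile) -> TrainingSelection:
    """MAD heuristic: nu = fraction of >3-MAD deviators, full set retained.

    MAD is the raw median absolute deviation (no 1.4826 scaling) and the
    comparison is strict, so a zero MAD flags only exact non-medians. A zero
    fraction is clamped up to 1/N, the smallest admissible nu.
    """
    s = profile.s
    med = float(np.median(s))
    mad = float(np.median(np.abs(s - med)))
    frac = float(np.mean(np.abs(s - med) > 3.0 * mad))
    nu = min(1.0, max(frac, 1.0 / profile.N))
    return TrainingSelection(np.arange(profile.N), nu=nu, method="mad")


def train_ocsvm(gram: GramMatrix | np.ndarray, nu: float,
                tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Solve the nu-OCSVM dual on a precomputed kernel.

    Returns (alpha, rho) with alpha over all supplied instances, rescaled to
    sum(alpha) = 1 and 0 <= alpha_i <= 1/(nu n); the decision function is
    f(q) = sum_i alpha_i k(x_i, q) - rho.
    """
    if not 0.0 < nu <= 1.0:
        raise ValueError("nu must lie in (0, 1]")
    K_mat = gram.values if isinstance(gram, GramMatrix) else np.asarray(gram, float)
    eigmin = float(np.linalg.eigvalsh(K_mat).min()) if K_mat.size else 0.0
    if eigmin < -1e-6:
        raise ValueError(
            f"Gram matrix is not PSD (min eigenvalue {eigmin:.3g}); "
            "add diagonal jitter before training")
    svm = OneClassSVM(kernel="precomputed", nu=nu, tol=tol)
    svm.fit(K_mat)
    n = K_mat.shape[0]
    alpha = np.zeros(n)
    alpha[svm.support_] = svm.dual_coef_.ravel()
    scale = alpha.sum()  # libsvm scales the dual so sum(alpha) = nu * n
    alpha /= scale
    rho = float(-svm.intercept_[0]) / scale
    return alpha, rho


@dataclass
class OneClassModel:
    """Trained one-class model over interaction-graph fingerprints."""

    alpha: np.ndarray
    rho: float
    nu: float
    kernel_mode: str
    vocabulary: Vocabulary
    training_fps: list[PathFingerprint]
    interaction_set: str = "hyd"
    method: str = "qms2"

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (len(self.training_fps),):
            raise ValueError("alpha length must match the retained training set")

    def score(self, graph: InteractionGraph) -> float:
        return score_graph(self, graph)

    def predict(self, graph: InteractionGraph) -> str:
        return predict(self, graph)

    def score_fingerprint(self, fp: PathFingerprint) -> float:
        k_vec = spkernel.cross(self.training_fps, fp, self.kernel_mode,
                               self.vocabulary)
        score = float(self.alpha @ k_vec - self.rho)
        # margin support vectors sit at 0 up to solver noise; snap so the
        # boundary-is-inlier convention is numerically stable
        return 0.0 if abs(score) < SCORE_EPS else score

    # -- persistence ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha.tolist(),
            "rho": self.rho,
            "nu": self.nu,
            "kernel_mode": self.kernel_mode,
            "interaction_set": self.interaction_set,
            "method": self.method,
            "vocabulary": json.loads(self.vocabulary.to_json()),
            "training_fps": [
                [[list(f.label_a), list(f.label_b), f.length, c]
                 for f, c in fp.items()]
                for fp in self.training_fps
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "OneClassModel":
        from .iggraph import NodeLabel
        from .spkernel import PathFeature

        obj = json.loads(text)
        fps = []
        for items in obj["training_fps"]:
            fp: PathFingerprint = PathFingerprint()
            for a, b, length, c in items:
                fp[PathFeature(NodeLabel(*a), NodeLabel(*b), int(length))] = int(c)
            fps.append(fp)
        vocab = Vocabulary.from_json(json.dumps(obj["vocabulary"]))
        return cls(np.array(obj["alpha"]), obj["rho"], obj["nu"],
                   obj["kernel_mode"], vocab, fps,
                   obj.get("interaction_set", "hyd"), obj.get("method", "qms2"))


def fit_model(train_fps: Sequence[PathFingerprint], method: str = "qms2",
              interaction_set: str = "hyd", sensitivity: float = 1.0,
              kernel_mode: str | None = None) -> OneClassModel:
    """Full training pipeline: Gram, KNN profile, nu heuristic, dual solve.

    ``method`` is one of ``qms2``, ``mad``, or ``nn`` (non-normalized kernel
    with QMS2 selection; NN models are trained with QMS2 only). The KNN
    profile uses the model's own kernel mode.
    """
    if method not in ("qms2", "mad", "nn"):
        raise ValueError("method must be 'qms2', 'mad', or 'nn'")
    if kernel_mode is None:
        kernel_mode = "nn" if method == "nn" else "normalized"
    fps = list(train_fps)
    vocab = Vocabulary.fit(fps)
    full_gram = spkernel.gram(fps, kernel_mode, vocab)
    profile = knn_profile(full_gram)
    if method == "mad":
        selection = mad_nu(profile)
    else:
        selection = qms2_select(profile, sensitivity)
    idx = selection.retained_indices
    sub = GramMatrix(full_gram.values[np.ix_(idx, idx)], kernel_mode)
    alpha, rho = train_ocsvm(sub, selection.nu)
    return OneClassModel(alpha, rho, selection.nu, kernel_mode, vocab,
                         [fps[i] for i in idx], interaction_set, method)


def score_graph(model: OneClassModel, graph: InteractionGraph) -> float:
    """Signed decision score of a query graph (negative = outlier)."""
    fp = spkernel.fingerprint(graph)
    if not fp:
        logger.warning("empty query graph; scored as outlier")
    return model.score_fingerprint(fp)


def predict(model: OneClassModel, graph: InteractionGraph) -> str:
    """'inlier' iff the signed score is >= 0, else 'outlier'."""
    return "inlier" if score_graph(model, graph) >= 0.0 else "outlier"


def training_outlier_fraction(model: OneClassModel) -> float:
    """Fraction of retained training instances scoring below the margin."""
    scores = np.array([model.score_fingerprint(fp) for fp in model.training_fps])
    return float(np.mean(scores < -SCORE_EPS))


def support_vector_fraction(model: OneClassModel) -> float:
    """Fraction of retained training instances with nonzero dual weight."""
    return float(np.mean(model.alpha > 0))
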