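"""Shared fixtures: synthetic templates, trajectories and small graphs."""

from __future__ import annotations

import numpy as np
import pytest

from igocsvm import iggraph, spkernel, synthdata
from igocsvm.iggraph import InteractionGraph, NodeLabel
from igocsvm.interactions import ITYPES


@pytest.fixture(scope="session")
def template():
    return synthdata.default_template()


@pytest.fixture(scope="session")
def small_trajectory(template):
    config = synthdata.SimConfig(n_frames=60, jitter_sigma=0.3,
                                 spurious_rate=0.5, seed=11)
    return synthdata.simulate_trajectory(template, config)


@pytest.fixture(scope="session")
def small_fps(small_trajectory):
    return [spkernel.fingerprint(iggraph.build_graph(f))
            for f in small_trajectory]


def random_complete_graph(rng: np.random.Generator,
                          max_nodes: int = 10) -> InteractionGraph:
    """Random complete labeled graph with deci-A weights in {1, 10..100}."""
    n = int(rng.integers(2, max_nodes + 1))
    labels = [NodeLabel(ITYPES[int(rng.integers(len(ITYPES)))],
                        ("ligand", "protein", "centre")[int(rng.integers(3))])
              for _ in range(n)]
    choices = np.concatenate([[1], np.arange(10, 101, 10)])
    w = choices[rng.integers(len(choices), size=(n, n))]
    w = np.triu(w, k=1)
    w = w + w.T
    return InteractionGraph(labels, w)


def floyd_warshall_oracle(weights: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs shortest paths (test oracle, O(n^3) loops)."""
    d = np.array(weights, dtype=float)
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d.astype(np.int64)


def nn_similarity_oracle(g1: InteractionGraph, g2: InteractionGraph) -> float:
    """Exhaustive feature-pair enumeration of the nn kernel (test oracle)."""
    def features(g):
        sp = floyd_warshall_oracle(g.weights)
        out = []
        for i in range(g.n_nodes):
            for j in range(i + 1, g.n_nodes):
                a, b = g.labels[i], g.labels[j]
                if b.sort_key() < a.sort_key():
                    a, b = b, a
                out.append((a, b, int(sp[i, j])))
        return out

    f1, f2 = features(g1), features(g2)
    return float(sum(1 for x in f1 for y in f2 if x == y))
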