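"""Weighted Louvain community detection with a resolution parameter.

The classic two-phase heuristic: greedy local node moves that increase
modularity, followed by aggregation of communities into supernodes, repeated
to fixation.  Modularity with resolution gamma is

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / 2m] * delta(c_i, c_j)

Aggregated matrices follow the congruence convention A' = O^T A O (one-hot
O), so a supernode's diagonal holds the doubled internal weight and the
modularity of a coarse partition equals the modularity of the induced fine
partition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityGraph

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


@dataclass
class Partition:
    """Community labels over a graph's nodes plus the achieved modularity."""

    labels: np.ndarray
    modularity_q: float
    resolution: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("labels must be a surjection onto 0..K-1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


def modularity(weights: np.ndarray, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Recompute Q for a labelling of a (possibly self-looped) weight matrix."""
    A = np.asarray(weights, dtype=float)
    labels = np.asarray(labels, dtype=int)
    m2 = A.sum()
    if m2 <= 0:
        raise ValueError("graph has no positive edge weight")
    k = A.sum(axis=1)
    n_comm = int(labels.max()) + 1
    onehot = np.zeros((A.shape[0], n_comm))
    onehot[np.arange(A.shape[0]), labels] = 1.0
    intra = float(np.einsum("ic,ij,jc->", onehot, A, onehot))
    sum_k = np.bincount(labels, weights=k, minlength=n_comm)
    return intra / m2 - resolution * float(np.sum((sum_k / m2) ** 2))


def _one_level(A: np.ndarray, resolution: float, rng: np.random.Generator) -> np.ndarray:
    """Greedy local moving on one aggregation level; returns compact labels."""
    n = A.shape[0]
    k = A.sum(axis=1)
    m2 = k.sum()
    comm = np.arange(n)
    sum_k = k.copy()
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            ci = comm[i]
            sum_k[ci] -= k[i]
            w = np.bincount(comm, weights=A[i], minlength=n)
            w[ci] -= A[i, i]  # self-loop weight travels with i, not with ci
            gain = w - resolution * k[i] * sum_k / m2
            best = int(np.argmax(gain))
            if gain[best] <= gain[ci] + 1e-12:
                best = ci
            comm[i] = best
            sum_k[best] += k[i]
            if best != ci:
                moved = True
    _, compact = np.unique(comm, return_inverse=True)
    return compact


def _aggregate(A: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n_comm = int(labels.max()) + 1
    onehot = np.zeros((A.shape[0], n_comm))
    onehot[np.arange(A.shape[0]), labels] = 1.0
    return onehot.T @ A @ onehot


def louvain(graph: SimilarityGraph | np.ndarray, resolution: float = 1.0,
            seed: "SeedLike" = 0) -> Partition:
    """Run Louvain on a weighted graph; node visit order is shuffled by seed.

    Returns a :class:`Partition` whose stored modularity is recomputed from
    the final labels on the original graph.  Q never decreases across
    passes (each accepted local move strictly increases it and aggregation
    preserves it).
    """
    A0 = graph.weights if isinstance(graph, SimilarityGraph) else np.asarray(graph, float)
    if A0.size == 0:
        raise ValueError("empty graph")
    if not (A0 > 0).any():
        raise ValueError("graph has no positive edge weight; nothing to cluster")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    rng = np.random.default_rng(seed)

    A = A0.copy()
    mapping = np.arange(A0.shape[0])
    while True:
        compact = _one_level(A, resolution, rng)
        n_comm = int(compact.max()) + 1
        if n_comm == A.shape[0]:
            break
        mapping = compact[mapping]
        A = _aggregate(A, compact)
    _, labels = np.unique(mapping, return_inverse=True)
    q = modularity(A0, labels, resolution)
    return Partition(labels=labels, modularity_q=q, resolution=resolution)
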