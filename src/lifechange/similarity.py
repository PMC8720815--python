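"""Participant similarity graphs over life-change item profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SimilarityGraph:
    """Dense weighted participant graph.

    ``weights`` is symmetric with zero diagonal and entries in [0, 1];
    ``node_ids`` carries the participant identifiers for each row/column.
    """

    node_ids: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != self.node_ids.size:
            raise ValueError("node_ids length must match weights")
        if not np.isfinite(w).all():
            raise ValueError("weights contain non-finite entries")
        if np.abs(w - w.T).max(initial=0.0) > 1e-12:
            raise ValueError("weights must be symmetric to 1e-12")
        if np.abs(np.diagonal(w)).max(initial=0.0) > 0:
            raise ValueError("self-loops are not allowed (diagonal must be 0)")
        if w.min(initial=0.0) < 0 or w.max(initial=0.0) > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.node_ids.size


def build_similarity_graph(
    item_matrix: pd.DataFrame | np.ndarray,
    node_ids: np.ndarray | None = None,
    standardize: bool = True,
) -> SimilarityGraph:
    """Correlation graph between participants' z-scored item vectors.

    Each edge weight is the Pearson correlation between two participants'
    per-column z-scored item vectors, with negative correlations truncated
    to 0 (classic modularity assumes non-negative weights).  Participants
    whose z-scored vector has zero variance are excluded with a warning, as
    their correlations are undefined.
    """
    if isinstance(item_matrix, pd.DataFrame):
        X = item_matrix.to_numpy(dtype=float)
        if node_ids is None:
            node_ids = item_matrix.index.to_numpy()
    else:
        X = np.asarray(item_matrix, dtype=float)
        if node_ids is None:
            node_ids = np.arange(X.shape[0])
    node_ids = np.asarray(node_ids)
    if np.isnan(X).any():
        raise ValueError("item matrix contains missing values; apply model-wise deletion first")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 participants")

    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        flat = sd == 0.0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} constant item column(s) contribute nothing "
                "to the similarity graph",
                stacklevel=2,
            )
        sd = np.where(flat, 1.0, sd)
        X = (X - mu) / sd

    row_sd = X.std(axis=1)
    keep = row_sd > 0
    if not keep.all():
        dropped = node_ids[~keep].tolist()
        warnings.warn(
            f"excluding {len(dropped)} participant(s) with zero item variance: "
            f"{dropped[:10]}",
            stacklevel=2,
        )
        X = X[keep]
        node_ids = node_ids[keep]
    if X.shape[0] < 3:
        raise ValueError("fewer than 3 usable participants after exclusions")

    corr = np.corrcoef(X)
    weights = np.clip(corr, 0.0, 1.0)
    weights = (weights + weights.T) / 2.0  # exact symmetry under float noise
    np.fill_diagonal(weights, 0.0)
    return SimilarityGraph(node_ids=node_ids, weights=weights)
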