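"""Bagging-enhanced Louvain subtyping of life-change stress profiles.

Participants are clustered on a correlation graph of their z-scored
life-change item vectors.  Louvain is stabilised by bootstrap aggregation:
the cohort is resampled with replacement B times, each resample is
re-clustered, and the fraction of resamples in which two participants are
co-clustered (among resamples containing both) forms a consensus
co-assignment matrix S.  The final subtypes are a Louvain partition of S
itself, so a single clustering paradigm is used end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .codebook import ItemCodebook
from .louvain import Partition, louvain
from .similarity import build_similarity_graph


class CoverageWarning(UserWarning):
    """Raised when some participant pairs were rarely co-sampled."""


@dataclass
class BaggedSubtypeSolution:
    """Consensus subtype solution for one cohort at one timepoint."""

    labels: pd.Series              # participant_id -> subtype id (0..K-1)
    coassignment: np.ndarray       # S, symmetric, unit diagonal
    node_ids: np.ndarray
    n_bootstraps: int
    seed: int
    resolution: float
    profiles: pd.DataFrame         # subtype x item, mean z-scored loadings
    names: list[str]
    merge_log: list[str] = field(default_factory=list)

    @property
    def n_subtypes(self) -> int:
        return self.profiles.shape[0]


@dataclass
class SubtypeMatch:
    """Optimal pairing of subtypes across two solutions by profile similarity."""

    correlation_matrix: pd.DataFrame      # rows: solution A, cols: solution B
    assignment: dict[int, int]            # A subtype -> B subtype (smaller set fully matched)
    matched_correlations: dict[tuple[int, int], float]


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def _profiles_from_labels(Z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    ks = np.unique(labels)
    return np.vstack([Z[labels == k].mean(axis=0) for k in ks])


def bagged_louvain(
    item_matrix: pd.DataFrame,
    n_bootstraps: int = 100,
    resolution: float = 1.0,
    seed: int = 0,
    codebook: ItemCodebook | None = None,
    min_subtype_frac: float = 0.05,
    merge_small: bool = True,
) -> BaggedSubtypeSolution:
    """Consensus Louvain subtyping via bootstrap aggregation.

    Parameters
    ----------
    item_matrix
        Complete participants x life-change-items frame (model-wise
        deletion applied by the caller); the index provides participant ids.
    n_bootstraps
        Number of with-replacement resamples (B >= 1).
    min_subtype_frac, merge_small
        Communities smaller than ``min_subtype_frac * n`` are merged into
        the larger subtype whose profile they correlate with most; every
        merge is logged and merging can be disabled.

    All randomness derives from ``seed``; bootstrap streams are spawned by
    counter, so runs are bit-reproducible.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    X = item_matrix.to_numpy(dtype=float)
    node_ids = item_matrix.index.to_numpy()
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"too few participants for resampling (n={n})")
    if np.isnan(X).any():
        raise ValueError("item matrix contains missing values")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_bootstraps + 1)
    coclust = np.zeros((n, n))
    copresent = np.zeros((n, n))

    for b in range(n_bootstraps):
        rng = np.random.default_rng(children[b])
        draw = rng.integers(0, n, size=n)
        uniq = np.unique(draw)
        if uniq.size < 3:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny resamples may drop flat rows
            graph = build_similarity_graph(X[uniq], node_ids=uniq)
        part = louvain(graph, resolution=resolution, seed=rng)
        kept = np.asarray(graph.node_ids, dtype=int)
        copresent[np.ix_(kept, kept)] += 1.0
        for c in range(part.n_communities):
            members = kept[part.labels == c]
            coclust[np.ix_(members, members)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(copresent > 0, coclust / np.maximum(copresent, 1.0), 0.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)

    off = ~np.eye(n, dtype=bool)
    low_cov = copresent[off] < 0.3 * n_bootstraps
    if low_cov.any():
        warnings.warn(
            f"{int(low_cov.sum() // 2)} participant pair(s) were co-sampled in "
            f"fewer than 30% of {n_bootstraps} resamples; consensus entries for "
            "those pairs are noisy",
            CoverageWarning,
            stacklevel=2,
        )

    consensus = S.copy()
    np.fill_diagonal(consensus, 0.0)
    final = louvain(consensus, resolution=resolution, seed=children[n_bootstraps])
    labels = final.labels.copy()

    Z = _zscore_columns(X)
    merge_log: list[str] = []
    if merge_small:
        labels, merge_log = _merge_small_communities(Z, labels, min_subtype_frac)

    labels = _relabel_by_size(labels)
    profiles = _profiles_from_labels(Z, labels)
    prof_df = pd.DataFrame(profiles, columns=list(item_matrix.columns))
    prof_df.index.name = "subtype"

    if codebook is not None:
        names = name_subtypes(prof_df, codebook)
    else:
        names = [f"Subtype {k + 1}" for k in range(prof_df.shape[0])]

    return BaggedSubtypeSolution(
        labels=pd.Series(labels, index=item_matrix.index, name="subtype"),
        coassignment=S,
        node_ids=node_ids,
        n_bootstraps=n_bootstraps,
        seed=seed,
        resolution=resolution,
        profiles=prof_df,
        names=names,
        merge_log=merge_log,
    )


def _merge_small_communities(
    Z: np.ndarray, labels: np.ndarray, min_frac: float
) -> tuple[np.ndarray, list[str]]:
    labels = labels.copy()
    n = labels.size
    log: list[str] = []
    min_size = max(2, int(np.ceil(min_frac * n)))
    while True:
        ks, sizes = np.unique(labels, return_counts=True)
        if ks.size <= 1:
            break
        small = ks[sizes < min_size]
        if small.size == 0:
            break
        # merge the smallest offender into its most-correlated large subtype
        k_small = small[np.argmin(sizes[np.isin(ks, small)])]
        profiles = {k: Z[labels == k].mean(axis=0) for k in ks}
        candidates = [k for k in ks if k != k_small]
        corrs = [
            float(np.corrcoef(profiles[k_small], profiles[k])[0, 1]) for k in candidates
        ]
        target = candidates[int(np.argmax(corrs))]
        log.append(
            f"merged subtype {int(k_small)} (n={int(sizes[ks == k_small][0])}) into "
            f"{int(target)} (profile r={max(corrs):.3f})"
        )
        labels[labels == k_small] = target
    _, labels = np.unique(labels, return_inverse=True)
    return labels, log


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as 0..K-1 in decreasing size (ties by old label)."""
    ks, sizes = np.unique(labels, return_counts=True)
    order = np.lexsort((ks, -sizes))
    remap = {int(ks[idx]): rank for rank, idx in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


def name_subtypes(profiles: pd.DataFrame, codebook: ItemCodebook) -> list[str]:
    """Descriptive subtype names from social vs economic mean loadings.

    Within each domain the subtypes' mean loadings are ranked; the extremes
    become "Lower" and "Higher", and a middle subtype is "Intermediate"
    only when it sits more than 0.1 z-units from both extremes (otherwise
    it takes the nearer extreme's label).  A single subtype is labelled by
    the sign of its mean loading.
    """
    social = codebook.domain_items("social")
    economic = codebook.domain_items("economic")
    if not social or not economic:
        raise ValueError("codebook must contain both social and economic life-change items")
    missing = [c for c in social + economic if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack domain items: {missing}")
    soc_levels = _domain_levels(profiles[social].mean(axis=1).to_numpy())
    eco_levels = _domain_levels(profiles[economic].mean(axis=1).to_numpy())
    return [f"{s} Social/{e} Economic" for s, e in zip(soc_levels, eco_levels)]


def _domain_levels(values: np.ndarray, gap: float = 0.1) -> list[str]:
    k = values.size
    if k == 1:
        return ["Lower" if values[0] < 0 else "Higher"]
    order = np.argsort(values, kind="stable")  # ties resolved by subtype index
    low, high = values[order[0]], values[order[-1]]
    if high - low <= 1e-12:
        warnings.warn(
            "identical domain means across subtypes; levels assigned by subtype index",
            stacklevel=3,
        )
    levels = [""] * k
    levels[order[0]] = "Lower"
    levels[order[-1]] = "Higher"
    for idx in order[1:-1]:
        v = values[idx]
        if k >= 3 and (v - low) > gap + 1e-9 and (high - v) > gap + 1e-9:
            levels[idx] = "Intermediate"
        else:
            levels[idx] = "Lower" if (v - low) <= (high - v) else "Higher"
    return levels


def relabel_to_reference(
    solution: BaggedSubtypeSolution, reference: BaggedSubtypeSolution
) -> tuple[pd.Series, dict[int, int]]:
    """Map a solution's subtype ids onto a reference solution's ids.

    Uses the optimal profile matching; subtypes without a counterpart in
    the reference (when the solution has more subtypes) keep new ids past
    the reference's range, with a warning rather than silent renumbering.
    """
    match = match_subtypes(solution, reference)
    mapping = dict(match.assignment)
    k_ref = reference.n_subtypes
    unmatched = [k for k in range(solution.n_subtypes) if k not in mapping]
    for i, k in enumerate(unmatched):
        warnings.warn(
            f"subtype {k} has no counterpart in the reference solution; "
            f"kept as new subtype {k_ref + i}",
            stacklevel=2,
        )
        mapping[k] = k_ref + i
    return solution.labels.map(mapping), mapping


def match_subtypes(
    solution_a: BaggedSubtypeSolution | pd.DataFrame,
    solution_b: BaggedSubtypeSolution | pd.DataFrame,
) -> SubtypeMatch:
    """Pair subtypes across two solutions by maximal summed profile correlation.

    The Pearson correlation between every cross-solution profile pair is
    computed; an optimal bipartite assignment (Hungarian algorithm) matches
    the smaller subtype set one-to-one into the larger.
    """
    prof_a = solution_a.profiles if isinstance(solution_a, BaggedSubtypeSolution) else solution_a
    prof_b = solution_b.profiles if isinstance(solution_b, BaggedSubtypeSolution) else solution_b
    if list(prof_a.columns) != list(prof_b.columns):
        raise ValueError("solutions must share an identical item set (and order)")
    A = prof_a.to_numpy(dtype=float)
    B = prof_b.to_numpy(dtype=float)
    ka, kb = A.shape[0], B.shape[0]
    corr = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            corr[i, j] = np.corrcoef(A[i], B[j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    assignment = {int(i): int(j) for i, j in zip(rows, cols)}
    matched = {(int(i), int(j)): float(corr[i, j]) for i, j in zip(rows, cols)}
    corr_df = pd.DataFrame(corr)
    corr_df.index.name = "subtype_a"
    corr_df.columns.name = "subtype_b"
    return SubtypeMatch(
        correlation_matrix=corr_df,
        assignment=assignment,
        matched_correlations=matched,
    )
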