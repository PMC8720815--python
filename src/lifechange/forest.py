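"""Regression forest with reduced-bias splits and conditional importance.

The forest approximates conditional-inference forests: at each node the
split variable is chosen by the strongest absolute association with the
node outcome (|Pearson r| for numeric candidates, the square root of the
ANOVA eta-squared for categorical ones — both on the same 0..1 scale),
which avoids the many-valued-predictor bias of raw CART gain.  Trees are
grown on *balanced* bootstraps: in-bag indices are dealt without
replacement from a replicated index pool, so every row appears the same
total number of times across the ensemble.

Variable importance permutes a predictor's out-of-bag values either
globally (marginal importance) or within a stratification grid built from
each tree's split points on correlated covariates (conditional importance,
in the style of Strobl's conditional permutation scheme), and reports the
mean increase in per-tree out-of-bag squared error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# predictor table


@dataclass
class PredictorTable:
    """Complete-case design matrix with mixed numeric/categorical columns.

    Categorical columns are stored as integer level codes (floats in ``X``);
    ``categories`` maps each categorical feature to its ordered level labels.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    is_categorical: np.ndarray
    categories: dict[str, list]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.is_categorical = np.asarray(self.is_categorical, dtype=bool)
        if self.X.shape != (self.y.size, len(self.feature_names)):
            raise ValueError("X shape inconsistent with y / feature_names")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("PredictorTable must be complete-case (no NaN)")

    @property
    def n_rows(self) -> int:
        return self.y.size

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        categorical: list[str] | None = None,
    ) -> "PredictorTable":
        """Build from a DataFrame, applying model-wise deletion.

        Object/category/bool dtype columns (plus any listed in
        ``categorical``) are factorised over their sorted unique levels.
        """
        if outcome not in frame.columns:
            raise ValueError(f"outcome column {outcome!r} not found")
        predictors = [c for c in frame.columns if c != outcome]
        complete = frame[predictors + [outcome]].dropna(axis=0, how="any")
        n_dropped = len(frame) - len(complete)
        categorical = set(categorical or [])
        for col in predictors:
            if complete[col].dtype == object or isinstance(
                complete[col].dtype, pd.CategoricalDtype
            ) or complete[col].dtype == bool:
                categorical.add(col)
        cols, is_cat, cats = [], [], {}
        for col in predictors:
            if col in categorical:
                levels = sorted(pd.unique(complete[col]).tolist())
                codes = complete[col].map({lvl: i for i, lvl in enumerate(levels)})
                cols.append(codes.to_numpy(dtype=float))
                cats[col] = levels
                is_cat.append(True)
            else:
                cols.append(complete[col].to_numpy(dtype=float))
                is_cat.append(False)
        return cls(
            X=np.column_stack(cols) if cols else np.empty((len(complete), 0)),
            y=complete[outcome].to_numpy(dtype=float),
            feature_names=list(predictors),
            is_categorical=np.asarray(is_cat, dtype=bool),
            categories=cats,
            n_dropped=n_dropped,
        )

    def select(self, features: list[str]) -> "PredictorTable":
        idx = [self.feature_names.index(f) for f in features]
        return PredictorTable(
            X=self.X[:, idx],
            y=self.y,
            feature_names=list(features),
            is_categorical=self.is_categorical[idx],
            categories={f: self.categories[f] for f in features if f in self.categories},
            n_dropped=self.n_dropped,
        )


# ---------------------------------------------------------------------------
# trees


@dataclass
class _Tree:
    feature: np.ndarray                  # -1 at leaves
    threshold: np.ndarray
    cat_left: list                        # per node: ndarray of level codes or None
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    split_points: dict[int, list]        # feature -> numeric cutpoints / level sets

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if self.feature[node] < 0:
                out[idx] = self.value[node]
                continue
            f = self.feature[node]
            if self.cat_left[node] is not None:
                go_left = np.isin(X[idx, f], self.cat_left[node])
            else:
                go_left = X[idx, f] <= self.threshold[node]
            if go_left.any():
                stack.append((self.left[node], idx[go_left]))
            if (~go_left).any():
                stack.append((self.right[node], idx[~go_left]))
        return out


def _association(x: np.ndarray, y: np.ndarray, is_cat: bool) -> float:
    """|Pearson r| (numeric) or sqrt(eta^2) from one-way ANOVA (categorical)."""
    if is_cat:
        codes = x.astype(int)
        counts = np.bincount(codes)
        present = counts > 0
        if present.sum() < 2:
            return 0.0
        sums = np.bincount(codes, weights=y)
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            return 0.0
        means = np.where(present, sums / np.maximum(counts, 1), 0.0)
        ssb = float(np.sum(counts[present] * (means[present] - y.mean()) ** 2))
        return math.sqrt(max(ssb, 0.0) / sst)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return abs(float(np.corrcoef(x, y)[0, 1]))


def _best_numeric_split(x: np.ndarray, y: np.ndarray, min_node: int):
    """Best SSE-reducing cutpoint leaving >= min_node rows per side."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    csum = np.cumsum(ys)
    csq = np.cumsum(ys**2)
    i = np.arange(1, n)  # left side sizes
    valid = (xs[1:] > xs[:-1]) & (i >= min_node) & (n - i >= min_node)
    if not valid.any():
        return None
    sse_l = csq[:-1] - csum[:-1] ** 2 / i
    tot_sum, tot_sq = csum[-1], csq[-1]
    sse_r = (tot_sq - csq[:-1]) - (tot_sum - csum[:-1]) ** 2 / (n - i)
    sse = np.where(valid, sse_l + sse_r, np.inf)
    best = int(np.argmin(sse))
    gain = (tot_sq - tot_sum**2 / n) - sse[best]
    threshold = (xs[best] + xs[best + 1]) / 2.0
    return gain, threshold


def _best_categorical_split(x: np.ndarray, y: np.ndarray, min_node: int):
    """Best binary level-set split, levels ordered by node outcome mean.

    Ordering levels by mean outcome and scanning contiguous prefixes is
    exact for squared-error regression splits.
    """
    codes = x.astype(int)
    levels = np.unique(codes)
    if levels.size < 2:
        return None
    means = np.array([y[codes == l].mean() for l in levels])
    order = np.argsort(means, kind="stable")
    rank = {int(levels[idx]): r for r, idx in enumerate(order)}
    xr = np.array([rank[int(c)] for c in codes], dtype=float)
    res = _best_numeric_split(xr, y, min_node)
    if res is None:
        return None
    gain, thr = res
    left_levels = np.array(
        [int(levels[idx]) for r, idx in enumerate(order) if r <= thr], dtype=float
    )
    return gain, left_levels


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    is_cat: np.ndarray,
    mtry: int,
    min_node: int,
    max_depth: int | None,
    rng: np.random.Generator,
) -> _Tree:
    feature: list[int] = []
    threshold: list[float] = []
    cat_left: list = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    split_points: dict[int, list] = {}
    p = X.shape[1]

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        cat_left.append(None)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        return len(feature) - 1

    def build(rows: np.ndarray, depth: int) -> int:
        node = new_node()
        ynode = y[rows]
        value[node] = float(ynode.mean())
        if (
            rows.size < 2 * min_node
            or ynode.std() == 0.0
            or (max_depth is not None and depth >= max_depth)
        ):
            return node
        cand = rng.choice(p, size=mtry, replace=False)
        cand.sort()
        assoc = np.array(
            [_association(X[rows, j], ynode, is_cat[j]) for j in cand]
        )
        # try candidates from strongest association down until a valid split
        for j in cand[np.argsort(-assoc, kind="stable")]:
            xj = X[rows, j]
            if is_cat[j]:
                res = _best_categorical_split(xj, ynode, min_node)
            else:
                res = _best_numeric_split(xj, ynode, min_node)
            if res is None or res[0] <= 0.0:
                continue
            _, split = res
            feature[node] = int(j)
            if is_cat[j]:
                cat_left[node] = np.asarray(split)
                split_points.setdefault(int(j), []).append(np.asarray(split))
                go_left = np.isin(xj, split)
            else:
                threshold[node] = float(split)
                split_points.setdefault(int(j), []).append(float(split))
                go_left = xj <= split
            left[node] = build(rows[go_left], depth + 1)
            right[node] = build(rows[~go_left], depth + 1)
            return node
        return node  # no informative candidate admitted a valid split

    build(np.asarray(rows), 0)
    return _Tree(
        feature=np.asarray(feature, dtype=int),
        threshold=np.asarray(threshold, dtype=float),
        cat_left=cat_left,
        left=np.asarray(left, dtype=int),
        right=np.asarray(right, dtype=int),
        value=np.asarray(value, dtype=float),
        split_points=split_points,
    )


# ---------------------------------------------------------------------------
# forest


@dataclass
class ForestModel:
    """Fitted balanced-bootstrap regression forest."""

    trees: list[_Tree]
    in_bag: list[np.ndarray]
    oob: list[np.ndarray]
    params: dict
    seed: int
    feature_names: list[str]
    is_categorical: np.ndarray
    n_rows: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)


DEFAULT_PARAMS = {
    "n_trees": 500,
    "mtry": None,            # ceil(sqrt(p)) when None
    "min_node_size": 5,
    "max_depth": None,
    "in_bag_frac": 0.632,
}


def _canonical_order(table: PredictorTable) -> PredictorTable:
    """Sort columns by feature name so fits are column-order invariant."""
    order = sorted(range(table.n_features), key=lambda i: table.feature_names[i])
    names = [table.feature_names[i] for i in order]
    return PredictorTable(
        X=table.X[:, order],
        y=table.y,
        feature_names=names,
        is_categorical=table.is_categorical[order],
        categories={f: table.categories[f] for f in names if f in table.categories},
        n_dropped=table.n_dropped,
    )


def fit_forest(table: PredictorTable, params: dict | None = None, seed: int = 0) -> ForestModel:
    """Fit the forest on a complete-case predictor table.

    Balanced bootstrap: ``n_trees * in_bag_size`` indices are dealt without
    replacement from a shuffled pool in which every row is replicated
    equally often, so total in-bag appearances are balanced across rows.
    All randomness flows from ``seed``.
    """
    cfg = dict(DEFAULT_PARAMS)
    cfg.update(params or {})
    table = _canonical_order(table)
    n, p = table.n_rows, table.n_features
    if n < 50:
        raise ValueError(f"need at least 50 complete rows (got {n})")
    if cfg["n_trees"] < 1:
        raise ValueError("n_trees must be >= 1")
    if table.y.std() == 0.0:
        raise ValueError("outcome is constant")
    mtry = cfg["mtry"] or math.ceil(math.sqrt(p))
    if mtry > p:
        raise ValueError(f"mtry ({mtry}) exceeds number of predictors ({p})")
    cfg["mtry"] = mtry

    n_trees = int(cfg["n_trees"])
    in_bag_size = max(1, round(cfg["in_bag_frac"] * n))
    total = n_trees * in_bag_size
    ss = np.random.SeedSequence(seed)
    rng_pool = np.random.default_rng(ss)
    # replicated index pool with per-row counts differing by at most one,
    # dealt without replacement into per-tree bags: balanced bootstrap
    base, extra = divmod(total, n)
    extras = rng_pool.choice(n, size=extra, replace=False)
    pool = np.concatenate([np.tile(np.arange(n), base), extras])
    rng_pool.shuffle(pool)
    bags = pool.reshape(n_trees, in_bag_size)

    tree_seeds = ss.spawn(n_trees)
    trees, in_bag, oob = [], [], []
    all_rows = np.arange(n)
    for t in range(n_trees):
        bag = bags[t]
        rng = np.random.default_rng(tree_seeds[t])
        tree = _grow_tree(
            table.X, table.y, bag, table.is_categorical,
            mtry, int(cfg["min_node_size"]), cfg["max_depth"], rng,
        )
        trees.append(tree)
        in_bag.append(bag)
        oob.append(np.setdiff1d(all_rows, bag, assume_unique=False))
    return ForestModel(
        trees=trees, in_bag=in_bag, oob=oob, params=cfg, seed=seed,
        feature_names=table.feature_names,
        is_categorical=table.is_categorical, n_rows=n,
    )


def predict(model: ForestModel, table: PredictorTable) -> np.ndarray:
    """Ensemble mean prediction (all trees)."""
    X = _canonical_order(table).X
    preds = np.zeros(X.shape[0])
    for tree in model.trees:
        preds += tree.predict(X)
    return preds / model.n_trees


def oob_predictions(model: ForestModel, table: PredictorTable) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag prediction per row and the count of contributing trees."""
    X = _canonical_order(table).X
    sums = np.zeros(X.shape[0])
    counts = np.zeros(X.shape[0])
    for tree, oob in zip(model.trees, model.oob):
        if oob.size == 0:
            continue
        sums[oob] += tree.predict(X[oob])
        counts[oob] += 1
    with np.errstate(invalid="ignore"):
        preds = sums / counts
    return preds, counts


def oob_r2(model: ForestModel, table: PredictorTable) -> float:
    """Out-of-bag R^2 = 1 - SS_res(OOB) / SS_tot.

    Rows that are never out-of-bag are dropped with a warning.
    """
    y = table.y
    if y.std() == 0.0:
        raise ValueError("outcome has zero variance")
    preds, counts = oob_predictions(model, table)
    covered = counts > 0
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} row(s) were never out-of-bag and are "
            "dropped from the OOB R^2",
            stacklevel=2,
        )
    yc, pc = y[covered], preds[covered]
    ss_res = float(np.sum((yc - pc) ** 2))
    ss_tot = float(np.sum((yc - yc.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# importance


def _cramers_v(x: np.ndarray, y: np.ndarray) -> float:
    """Cramer's V between two code vectors (bias-uncorrected)."""
    table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    if min(table.shape) < 2:
        return 0.0
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    n = table.sum()
    return math.sqrt(chi2 / (n * (min(table.shape) - 1)))


def _bin_numeric(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(x, edges)


def predictor_association_matrix(table: PredictorTable) -> np.ndarray:
    """Pairwise predictor association on a common 0..1 scale.

    |Pearson r| between numeric pairs; Cramer's V for pairs involving a
    categorical predictor (numeric members are quartile-binned first).
    """
    p = table.n_features
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            xi, xj = table.X[:, i], table.X[:, j]
            ci, cj = table.is_categorical[i], table.is_categorical[j]
            if not ci and not cj:
                val = 0.0 if xi.std() == 0 or xj.std() == 0 else abs(
                    float(np.corrcoef(xi, xj)[0, 1])
                )
            else:
                a = xi.astype(int) if ci else _bin_numeric(xi)
                b = xj.astype(int) if cj else _bin_numeric(xj)
                val = _cramers_v(a, b)
            out[i, j] = out[j, i] = val
    return out


def _grid_cells(tree: _Tree, X_oob: np.ndarray, cond_idx: list[int]) -> np.ndarray:
    """Cell id per OOB row from the tree's split points on the conditioning set."""
    n = X_oob.shape[0]
    if not cond_idx:
        return np.zeros(n, dtype=int)
    comps = []
    for z in cond_idx:
        splits = tree.split_points.get(z)
        if not splits:
            continue
        if isinstance(splits[0], float):
            cuts = np.unique(np.asarray(splits, dtype=float))
            comps.append(np.digitize(X_oob[:, z], cuts))
        else:
            for left_set in splits:
                comps.append(np.isin(X_oob[:, z], left_set).astype(int))
    if not comps:
        return np.zeros(n, dtype=int)
    stacked = np.column_stack(comps)
    _, cells = np.unique(stacked, axis=0, return_inverse=True)
    return cells


def _permute_within(x: np.ndarray, cells: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = x.copy()
    for cell in np.unique(cells):
        idx = np.nonzero(cells == cell)[0]
        if idx.size > 1:
            out[idx] = x[idx[rng.permutation(idx.size)]]
    return out


@dataclass
class ImportanceTable:
    """Conditional and marginal permutation importance per predictor."""

    table: pd.DataFrame            # feature, conditional, marginal, rank, conditioning_set
    assoc_threshold: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def conditional_importance(
    model: ForestModel,
    table: PredictorTable,
    assoc_threshold: float = 0.2,
    n_permutations: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """Conditional and marginal permutation importance for every predictor.

    For predictor j the conditioning set holds every other predictor whose
    association with j exceeds ``assoc_threshold``; per tree, j's
    out-of-bag values are permuted within the cells of a grid built from
    that tree's split points on the conditioning set.  Importance is the
    mean over trees of the permuted-minus-original OOB mean squared error
    (negative values are reported as-is).
    """
    if not (0.0 <= assoc_threshold <= 1.0):
        raise ValueError("assoc_threshold must lie in [0, 1]")
    table = _canonical_order(table)
    if table.feature_names != model.feature_names:
        raise ValueError("table features do not match the fitted model")
    if all(o.size == 0 for o in model.oob):
        raise ValueError("model has no out-of-bag rows")
    X, y = table.X, table.y
    p = table.n_features
    assoc = predictor_association_matrix(table)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    base_mse = []
    oob_X = []
    for tree, oob in zip(model.trees, model.oob):
        if oob.size == 0:
            base_mse.append(np.nan)
            oob_X.append(None)
            continue
        resid = tree.predict(X[oob]) - y[oob]
        base_mse.append(float(np.mean(resid**2)))
        oob_X.append(X[oob])

    cond = np.zeros(p)
    marg = np.zeros(p)
    cond_sets: list[list[str]] = []
    for j in range(p):
        zset = [k for k in range(p) if k != j and assoc[j, k] > assoc_threshold]
        cond_sets.append([table.feature_names[k] for k in zset])
        deltas_c, deltas_m = [], []
        for t, (tree, oob) in enumerate(zip(model.trees, model.oob)):
            if oob.size == 0:
                continue
            Xo = oob_X[t]
            yo = y[oob]
            cells = _grid_cells(tree, Xo, zset)
            global_cells = np.zeros(Xo.shape[0], dtype=int)
            mse_c = mse_m = 0.0
            for _ in range(n_permutations):
                for cells_r, acc in ((cells, "c"), (global_cells, "m")):
                    Xp = Xo.copy()
                    Xp[:, j] = _permute_within(Xo[:, j], cells_r, rng)
                    mse = float(np.mean((tree.predict(Xp) - yo) ** 2))
                    if acc == "c":
                        mse_c += mse
                    else:
                        mse_m += mse
            deltas_c.append(mse_c / n_permutations - base_mse[t])
            deltas_m.append(mse_m / n_permutations - base_mse[t])
        cond[j] = float(np.mean(deltas_c))
        marg[j] = float(np.mean(deltas_m))

    order = np.argsort(-cond, kind="stable")
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    frame = pd.DataFrame(
        {
            "feature": table.feature_names,
            "conditional_importance": cond,
            "marginal_importance": marg,
            "rank": ranks,
            "conditioning_set": [";".join(s) for s in cond_sets],
        }
    ).sort_values("rank").reset_index(drop=True)
    return ImportanceTable(table=frame, assoc_threshold=assoc_threshold,
                           n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# model variants


def build_model_variants(
    frame: pd.DataFrame,
    outcome: str,
    base_predictors: list[str],
    subtype_col: str,
    item_cols: list[str],
    oxcgrt_cols: list[str] | None = None,
    us_mask: pd.Series | None = None,
    categorical: list[str] | None = None,
) -> dict[str, PredictorTable]:
    """The three predictor-table variants of the forest analysis.

    A: base predictors + subtype as one categorical column.
    B: base predictors + the individual life-change items (subtype removed).
    C: variant A restricted to US rows, plus the policy-index averages
       (requires ``oxcgrt_cols`` and ``us_mask``; errors without US rows).
    """
    for col in base_predictors + [subtype_col, outcome]:
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    categorical = list(categorical or [])
    cat_a = categorical + [subtype_col]
    variants: dict[str, PredictorTable] = {}
    cols_a = base_predictors + [subtype_col, outcome]
    variants["A"] = PredictorTable.from_frame(frame[cols_a], outcome, categorical=cat_a)

    missing_items = [c for c in item_cols if c not in frame.columns]
    if missing_items:
        raise ValueError(f"missing life-change item columns: {missing_items}")
    cols_b = base_predictors + item_cols + [outcome]
    variants["B"] = PredictorTable.from_frame(frame[cols_b], outcome, categorical=categorical)

    if oxcgrt_cols is not None:
        if us_mask is None:
            raise ValueError("variant C requires a US-row mask")
        missing_ix = [c for c in oxcgrt_cols if c not in frame.columns]
        if missing_ix:
            raise ValueError(f"missing policy-index columns: {missing_ix}")
        us_frame = frame[us_mask.reindex(frame.index, fill_value=False)]
        if us_frame.empty:
            raise ValueError("variant C requested but the dataset has no US rows")
        cols_c = base_predictors + [subtype_col] + oxcgrt_cols + [outcome]
        variants["C"] = PredictorTable.from_frame(
            us_frame[cols_c], outcome, categorical=cat_a
        )
    return variants
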