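"""Subtype stability, wave-to-wave transitions and per-path score changes.

Given matched subtype labels at two consecutive waves, participants are
cross-tabulated into transition paths; for each path the within-person
change in a scale score (mood, worries) is tested with a paired t-test and
annotated with conventional significance stars.  Group comparisons across
subtypes (one-way ANOVA, chi-square) mirror standard survey reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TransitionSummary:
    """Subtype flows between two waves plus per-path change statistics."""

    counts: pd.DataFrame                 # from-subtype x to-subtype
    n_completers: int
    n_excluded: int
    paths: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def stability_fraction(self) -> float:
        common = [k for k in self.counts.index if k in self.counts.columns]
        diag = sum(self.counts.loc[k, k] for k in common)
        return float(diag) / self.n_completers if self.n_completers else float("nan")


def star_level(p: float) -> str:
    """Significance stars: * p<.05, ** p<.01, *** p<.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def tally_transitions(labels_t1: pd.Series, labels_t2: pd.Series) -> TransitionSummary:
    """Cross-tabulate matched subtype labels of participants in both waves.

    Participants missing at either wave are excluded from the table and
    reported in ``n_excluded``.  Counts always sum to the completer n.
    """
    a = labels_t1.dropna()
    b = labels_t2.dropna()
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError("no participants present at both waves")
    n_excluded = len(a.index.union(b.index)) - len(common)
    counts = pd.crosstab(a.loc[common], b.loc[common])
    all_labels = sorted(set(counts.index) | set(counts.columns))
    counts = counts.reindex(index=all_labels, columns=all_labels, fill_value=0)
    counts.index.name = "from_subtype"
    counts.columns.name = "to_subtype"
    return TransitionSummary(counts=counts, n_completers=len(common), n_excluded=n_excluded)


def paired_t_test(x_before: np.ndarray, x_after: np.ndarray) -> dict:
    """One-sample t-test on within-person differences (after - before).

    Returns ``t``, ``df``, two-sided ``p``, the mean difference and n.
    Zero variance of the differences is flagged (``p`` undefined) rather
    than silently reported.
    """
    before = np.asarray(x_before, dtype=float)
    after = np.asarray(x_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(before) & np.isfinite(after)
    d = after[ok] - before[ok]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    mean = float(d.mean())
    if sd == 0.0:
        return {"t": np.nan, "df": n - 1, "p": np.nan, "mean_diff": mean,
                "n": n, "zero_variance": True}
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"t": float(t), "df": n - 1, "p": float(p), "mean_diff": mean,
            "n": n, "zero_variance": False}


def change_by_path(
    transitions: TransitionSummary,
    labels_t1: pd.Series,
    labels_t2: pd.Series,
    scores_before: pd.Series,
    scores_after: pd.Series,
    score_name: str,
    bh_adjust: bool = False,
) -> TransitionSummary:
    """Per-path mean score change with paired t-tests and stars.

    Appends rows for ``score_name`` to ``transitions.paths``.  Paths with a
    single member are reported without a test; raw p-values are starred
    (Benjamini-Hochberg adjustment available but off by default, matching
    the starred-raw-p convention of the transition figure).
    """
    a = labels_t1.dropna()
    b = labels_t2.dropna()
    common = a.index.intersection(b.index)
    rows = []
    for frm in transitions.counts.index:
        for to in transitions.counts.columns:
            if transitions.counts.loc[frm, to] == 0:
                continue
            members = common[(a.loc[common] == frm) & (b.loc[common] == to)]
            sb = scores_before.reindex(members)
            sa = scores_after.reindex(members)
            ok = sb.notna() & sa.notna()
            n_ok = int(ok.sum())
            row = {"from_subtype": frm, "to_subtype": to, "score": score_name, "n": n_ok}
            if n_ok >= 2:
                res = paired_t_test(sb[ok].to_numpy(), sa[ok].to_numpy())
                row.update(
                    estimate=res["mean_diff"], t=res["t"], df=res["df"], p=res["p"],
                    zero_variance=res["zero_variance"],
                )
            else:
                row.update(estimate=float(sa[ok].mean() - sb[ok].mean()) if n_ok else np.nan,
                           t=np.nan, df=np.nan, p=np.nan, zero_variance=False)
            rows.append(row)
    paths = pd.DataFrame(rows)
    if bh_adjust and paths["p"].notna().any():
        mask = paths["p"].notna()
        paths.loc[mask, "p"] = stats.false_discovery_control(paths.loc[mask, "p"], method="bh")
    paths["stars"] = [star_level(p) for p in paths["p"]]
    combined = pd.concat([transitions.paths, paths], ignore_index=True)
    return TransitionSummary(
        counts=transitions.counts,
        n_completers=transitions.n_completers,
        n_excluded=transitions.n_excluded,
        paths=combined,
    )


def group_compare(values: np.ndarray, groups: np.ndarray) -> dict:
    """One-way ANOVA across groups; groups with < 2 observations are excluded."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    samples = []
    for g in pd.unique(groups):
        x = values[groups == g]
        if x.size < 2:
            warnings.warn(f"excluding group {g!r} with fewer than 2 observations",
                          stacklevel=2)
            continue
        samples.append(x)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    F, p = stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = sum(x.size for x in samples) - len(samples)
    return {"F": float(F), "df1": df1, "df2": df2, "p": float(p)}


def chi_square(table: np.ndarray) -> dict:
    """Pearson chi-square of independence without continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    res = stats.chi2_contingency(table, correction=False)
    return {"X2": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue)}
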