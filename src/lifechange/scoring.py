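"""Item recoding, scale scoring and lightweight reliability diagnostics.

Mood (10 items) and COVID-worries (6 items) scale scores are arithmetic
means of the recoded 1-5 items, so each score lives on the same 1-5 range
with higher values meaning worse mood / more worry.  A score is missing
whenever any constituent item is missing (model-wise deletion); prorated
means are deliberately not offered.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .codebook import ItemCodebook
from .datasets import ID_COL, TIME_COL, SurveyDataset


def recode_items(dataset: SurveyDataset, codebook: ItemCodebook) -> SurveyDataset:
    """Reflect reverse-keyed items: x -> (scale_min + scale_max) - x.

    Normally keyed items pass through; missing responses stay missing.
    Responses outside an item's ordinal range raise, naming the offending
    rows and column.  Applying the recode twice restores the input.
    """
    out = dataset.copy()
    for name in out.item_columns(codebook):
        item = codebook[name]
        col = out.data[name]
        bad = col.notna() & ((col < item.scale_min) | (col > item.scale_max))
        if bad.any():
            rows = out.data.index[bad].tolist()[:5]
            raise ValueError(
                f"out-of-range responses in column {name!r} at rows {rows} "
                f"(allowed {item.scale_min}..{item.scale_max})"
            )
        if item.direction == "reversed":
            out.data[name] = item.scale_min + item.scale_max - col
    return out


def compute_scale_score(
    dataset: SurveyDataset, codebook: ItemCodebook, battery: str
) -> pd.DataFrame:
    """Scale scores for one battery, one row per (participant, timepoint).

    Returns columns ``participant_id, timepoint, scale, value,
    n_items_used``; ``value`` is NaN when any item is missing.  The input
    is expected to be recoded already (see :func:`recode_items`).
    """
    items = codebook.battery_items(battery)
    if len(items) < 2:
        raise ValueError(f"battery {battery!r} has fewer than 2 items")
    missing = [c for c in items if c not in dataset.data.columns]
    if missing:
        raise ValueError(f"dataset lacks items for battery {battery!r}: {missing}")
    block = dataset.data[items]
    n_used = block.notna().sum(axis=1)
    value = block.mean(axis=1).where(n_used == len(items))
    return pd.DataFrame(
        {
            ID_COL: dataset.data[ID_COL],
            TIME_COL: dataset.data[TIME_COL],
            "scale": battery,
            "value": value,
            "n_items_used": n_used.astype(int),
        }
    )


def attach_scores(dataset: SurveyDataset, codebook: ItemCodebook) -> SurveyDataset:
    """Recode items and append ``mood_score`` / ``worries_score`` columns."""
    recoded = recode_items(dataset, codebook)
    for battery, col in (("mood", "mood_score"), ("worries", "worries_score")):
        scores = compute_scale_score(recoded, codebook, battery)
        recoded.data[col] = scores["value"].to_numpy()
    return recoded


def reliability_diagnostics(item_matrix: pd.DataFrame) -> dict[str, float]:
    """Cronbach's alpha and first-eigenvalue variance fraction.

    ``alpha = k/(k-1) * (1 - sum(var_i)/var_total)`` on complete rows;
    ``first_eigen_fraction`` is the leading eigenvalue of the item
    correlation matrix divided by the number of items.  Together these are
    a quick unidimensionality check for a battery that is scored by simple
    averaging.  Zero-variance items are excluded with a warning.
    """
    mat = pd.DataFrame(item_matrix).dropna(axis=0, how="any")
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 items")
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    variances = mat.var(axis=0, ddof=1)
    zero = variances.index[variances == 0.0].tolist()
    if zero:
        warnings.warn(f"excluding zero-variance items: {zero}", stacklevel=2)
        mat = mat.drop(columns=zero)
        if mat.shape[1] < 2:
            raise ValueError("fewer than 2 items remain after exclusions")
        variances = variances.drop(zero)

    k = mat.shape[1]
    total_var = mat.sum(axis=1).var(ddof=1)
    alpha = (k / (k - 1)) * (1.0 - variances.sum() / total_var)

    corr = np.corrcoef(mat.to_numpy(float), rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)
    first_fraction = float(eigvals[-1] / k)
    return {"alpha": float(alpha), "first_eigen_fraction": first_fraction}
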