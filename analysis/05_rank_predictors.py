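"""Predict follow-up mood with the conditional forest and rank predictors.

Fits the three model variants — A: mid-wave scores, demographics and the
derived subtype; B: subtype replaced by the 14 individual life-change
items; C: variant A on US rows plus window-averaged state policy/threat
indices — reports out-of-bag R^2 per variant and the conditional vs
marginal permutation importance ranking, and checks that the planted
predictors (prior mood, worries, subtype) outrank the pure-noise columns.
"""

import warnings
from pathlib import Path

import pandas as pd

import lifechange as lc
from lifechange.oxcgrt import INDEX_COLS, join_indices, window_average
from lifechange.synthetic import simulate_oxcgrt

OUT = Path("results/analysis")
SEED = 23

def main() -> None:
    scored = lc.SurveyDataset.from_csv(OUT / "scored.csv",
                                       ["april", "may", "november"])
    codebook = lc.ItemCodebook.from_csv(OUT / "codebook.csv")
    labels = pd.read_csv(OUT / "subtype_labels.csv")
    items = codebook.battery_items("life_change")

    may, nov = scored.wave("may"), scored.wave("november")
    frame = pd.DataFrame(index=may.index)
    frame["prior_mood"] = may["mood_score"]
    frame["worries"] = may["worries_score"]
    for col in ("sex", "age_group", "country", "essential_worker"):
        frame[col] = may[col]
    noise_cols = [c for c in may.columns if c.startswith("noise_")]
    frame[noise_cols] = may[noise_cols]
    frame["subtype"] = (
        labels[labels.timepoint == "may"]
        .set_index("participant_id")["subtype"]
        .reindex(frame.index)
        .astype(float)
    )
    frame[items] = may[items]
    frame["outcome"] = nov["mood_followup"].reindex(frame.index)

    series = simulate_oxcgrt(seed=SEED)
    means = window_average(series, "2020-04-01", "2020-05-31")
    joined = join_indices(may[["state", "country"]].copy(), means)
    frame[INDEX_COLS] = joined[INDEX_COLS]

    variants = lc.build_model_variants(
        frame,
        outcome="outcome",
        base_predictors=["prior_mood", "worries", "sex", "age_group", "country",
                         "essential_worker"] + noise_cols,
        subtype_col="subtype",
        item_cols=items,
        oxcgrt_cols=INDEX_COLS,
        us_mask=may["country"] == "US",
        categorical=["sex", "age_group", "country"],
    )

    for name, table in variants.items():
        model = lc.fit_forest(table, {"n_trees": 150}, seed=SEED)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = lc.oob_r2(model, table)
        imp = lc.conditional_importance(model, table, n_permutations=3, seed=SEED)
        imp.to_frame().to_csv(OUT / f"importance_{name}.csv", index=False)
        top = imp.to_frame().head(5)
        print(f"\nvariant {name}: n={table.n_rows}, p={table.n_features}, "
              f"OOB R^2 = {r2:.3f}")
        print(top[["feature", "conditional_importance", "marginal_importance",
                   "rank"]].to_string(index=False, float_format="%.4f"))
        noise_rank = imp.to_frame().set_index("feature")["rank"]
        present_noise = [c for c in noise_cols if c in noise_rank.index]
        if present_noise:
            best_noise = noise_rank.loc[present_noise].min()
            print(f"best-ranked noise predictor: rank {int(best_noise)}")

    print(f"\nwrote importance_A/B/C.csv to {OUT}/")

if __name__ == "__main__":
    main()
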