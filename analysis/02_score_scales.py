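"""Score the mood and worries batteries and check their internal consistency.

Recodes reverse-keyed items, averages each battery to a 1-5 scale score
(missing whenever any constituent item is missing), and reports Cronbach's
alpha plus the first-eigenvalue variance fraction per battery and wave —
the quick unidimensionality check that justifies scoring by simple
averaging.  Appends scores to the dataset and writes a reliability table.
"""

from pathlib import Path

import pandas as pd

import lifechange as lc

OUT = Path("results/analysis")

def main() -> None:
    dataset = lc.SurveyDataset.from_csv(OUT / "dataset.csv",
                                        ["april", "may", "november"])
    codebook = lc.ItemCodebook.from_csv(OUT / "codebook.csv")
    scored = lc.attach_scores(dataset, codebook)
    scored.to_csv(OUT / "scored.csv")

    rows = []
    for battery in ("mood", "worries", "life_change"):
        items = codebook.battery_items(battery)
        for wave in scored.timepoints:
            mat = scored.item_matrix(wave, items, complete_only=True)
            diag = lc.reliability_diagnostics(mat)
            rows.append({"battery": battery, "wave": wave, "n": len(mat), **diag})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "reliability.csv", index=False)

    print(table.to_string(index=False, float_format="%.3f"))
    may = scored.wave("may")
    print(f"\nmay mood score: mean {may['mood_score'].mean():.2f} "
          f"(sd {may['mood_score'].std():.2f}), "
          f"worries: mean {may['worries_score'].mean():.2f} "
          f"(sd {may['worries_score'].std():.2f})")
    print(f"wrote scored.csv and reliability.csv to {OUT}/")

if __name__ == "__main__":
    main()
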