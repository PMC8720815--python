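"""End-to-end orchestration: simulate/load -> score -> subtype -> transitions -> forest.

Every stage draws its seed deterministically from the master seed, applies
model-wise deletion for its own variable set, and reports exact row
accounting (input = analyzed + deleted) into a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codebook import ItemCodebook, default_codebook
from .datasets import SurveyDataset
from .forest import (
    build_model_variants,
    conditional_importance,
    fit_forest,
    oob_r2,
)
from .longitudinal import change_by_path, tally_transitions
from .oxcgrt import INDEX_COLS, join_indices, load_series, window_average
from .scoring import attach_scores
from .subtyping import (
    BaggedSubtypeSolution,
    bagged_louvain,
    match_subtypes,
    relabel_to_reference,
)
from .synthetic import GeneratorConfig, generate_population, simulate_oxcgrt

logger = logging.getLogger(__name__)

BASE_PREDICTORS = ["prior_mood", "worries", "sex", "age_group", "country", "essential_worker"]
CATEGORICAL_PREDICTORS = ["sex", "age_group", "country"]
OXCGRT_WINDOW = ("2020-04-01", "2020-05-31")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``dataset_csv`` (with optional ``codebook_csv``) or
    ``generator`` must be supplied.
    """

    dataset_csv: str | None = None
    codebook_csv: str | None = None
    generator: GeneratorConfig | None = None
    oxcgrt_csv: str | None = None
    simulate_oxcgrt_series: bool = False
    timepoints: list[str] = field(default_factory=lambda: ["april", "may", "november"])
    n_bootstraps: int = 100
    resolution: float = 1.0
    min_subtype_frac: float = 0.05
    forest_params: dict = field(default_factory=dict)
    assoc_threshold: float = 0.2
    n_permutations: int = 5
    seed: int = 0
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if (self.dataset_csv is None) == (self.generator is None):
            raise ValueError("supply exactly one of dataset_csv or generator")
        for path in (self.dataset_csv, self.codebook_csv, self.oxcgrt_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        return cls(generator=gen, **raw)


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the output bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {"generator": seeds[0], "subtyping": seeds[1],
                        "forest": seeds[2], "importance": seeds[3],
                        "oxcgrt": seeds[4]},
        "parameters": {
            "n_bootstraps": config.n_bootstraps,
            "resolution": config.resolution,
            "min_subtype_frac": config.min_subtype_frac,
            "forest_params": dict(config.forest_params),
            "assoc_threshold": config.assoc_threshold,
            "n_permutations": config.n_permutations,
        },
        "stages": {},
        "files": [],
    }
    stage = "setup"
    try:
        # ---------------------------------------------------------- data
        stage = "data"
        cb = (
            ItemCodebook.from_csv(config.codebook_csv)
            if config.codebook_csv
            else default_codebook()
        )
        if config.generator is not None:
            gen_cfg = dataclasses.replace(config.generator, seed=seeds[0])
            dataset, truth = generate_population(gen_cfg)
            truth.to_json(outdir / "truth.json")
            dataset.to_csv(outdir / "dataset.csv")
            manifest["files"] += ["truth.json", "dataset.csv"]
        else:
            dataset = SurveyDataset.from_csv(config.dataset_csv, config.timepoints)
            truth = None
        tps = dataset.timepoints
        logger.info("stage data: %d participants, %d waves", dataset.n_participants, len(tps))
        manifest["stages"]["data"] = {
            "input_n": dataset.n_participants,
            "analyzed_n": dataset.n_participants,
            "deleted_n": 0,
        }

        # ------------------------------------------------------- scoring
        stage = "scoring"
        scored = attach_scores(dataset, cb)
        scored.data.to_csv(outdir / "scores.csv", index=False)
        manifest["files"].append("scores.csv")

        # ----------------------------------------------------- subtyping
        stage = "subtyping"
        lc_items = cb.battery_items("life_change")
        solutions: dict[str, BaggedSubtypeSolution] = {}
        sub_accounting = {}
        for i, tp in enumerate(tps):
            mat = scored.item_matrix(tp, lc_items, complete_only=True)
            n_wave = scored.wave(tp).shape[0]
            sol = bagged_louvain(
                mat,
                n_bootstraps=config.n_bootstraps,
                resolution=config.resolution,
                seed=seeds[1] + i,
                codebook=cb,
                min_subtype_frac=config.min_subtype_frac,
            )
            solutions[tp] = sol
            sub_accounting[tp] = {
                "input_n": int(n_wave),
                "analyzed_n": int(mat.shape[0]),
                "deleted_n": int(n_wave - mat.shape[0]),
                "n_subtypes": sol.n_subtypes,
                "names": sol.names,
                "merge_log": sol.merge_log,
            }
            sol.profiles.to_csv(outdir / f"profiles_{tp}.csv")
            pd.DataFrame(
                sol.coassignment, index=sol.node_ids, columns=sol.node_ids
            ).to_csv(outdir / f"coassignment_{tp}.csv")
            manifest["files"] += [f"profiles_{tp}.csv", f"coassignment_{tp}.csv"]
        manifest["stages"]["subtyping"] = sub_accounting

        # ------------------------------------------------------ matching
        stage = "matching"
        ref_tp = tps[1] if len(tps) > 1 else tps[0]
        matched_labels: dict[str, pd.Series] = {}
        match_rows = []
        for tp in tps:
            if tp == ref_tp:
                matched_labels[tp] = solutions[tp].labels
                continue
            labels, mapping = relabel_to_reference(solutions[tp], solutions[ref_tp])
            matched_labels[tp] = labels
            match = match_subtypes(solutions[tp], solutions[ref_tp])
            for (a, b), corr in match.matched_correlations.items():
                match_rows.append(
                    {"wave": tp, "reference": ref_tp, "subtype": a,
                     "matched_to": mapping[a], "profile_correlation": corr}
                )
        pd.DataFrame(match_rows).to_csv(outdir / "matches.csv", index=False)
        manifest["files"].append("matches.csv")

        labels_long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "participant_id": matched_labels[tp].index,
                        "timepoint": tp,
                        "subtype": matched_labels[tp].to_numpy(),
                        "name": [
                            solutions[ref_tp].names[s]
                            if s < len(solutions[ref_tp].names)
                            else f"Subtype {s + 1}"
                            for s in matched_labels[tp]
                        ],
                    }
                )
                for tp in tps
            ],
            ignore_index=True,
        )
        labels_long.to_csv(outdir / "labels.csv", index=False)
        manifest["files"].append("labels.csv")

        # --------------------------------------------------- transitions
        stage = "transitions"
        trans_frames = []
        trans_accounting = {}
        for t in range(len(tps) - 1):
            tp_a, tp_b = tps[t], tps[t + 1]
            summary = tally_transitions(matched_labels[tp_a], matched_labels[tp_b])
            wave_a, wave_b = scored.wave(tp_a), scored.wave(tp_b)
            for score_col, score_name in (("mood_score", "mood"), ("worries_score", "worries")):
                summary = change_by_path(
                    summary, matched_labels[tp_a], matched_labels[tp_b],
                    wave_a[score_col], wave_b[score_col], score_name,
                )
            paths = summary.paths.copy()
            paths.insert(0, "pair", f"{tp_a}->{tp_b}")
            trans_frames.append(paths)
            trans_accounting[f"{tp_a}->{tp_b}"] = {
                "input_n": summary.n_completers + summary.n_excluded,
                "analyzed_n": summary.n_completers,
                "deleted_n": summary.n_excluded,
                "stability_fraction": summary.stability_fraction,
            }
            counts = summary.counts.stack().rename("n").reset_index()
            counts.insert(0, "pair", f"{tp_a}->{tp_b}")
            counts.to_csv(outdir / f"transitions_{tp_a}_{tp_b}.csv", index=False)
            manifest["files"].append(f"transitions_{tp_a}_{tp_b}.csv")
        pd.concat(trans_frames, ignore_index=True).to_csv(
            outdir / "transitions_long.csv", index=False
        )
        manifest["files"].append("transitions_long.csv")
        manifest["stages"]["transitions"] = trans_accounting

        # -------------------------------------------------------- forest
        stage = "forest"
        mid_tp, last_tp = ref_tp, tps[-1]
        mid = scored.wave(mid_tp)
        last = scored.wave(last_tp)
        frame = pd.DataFrame(index=mid.index)
        frame["prior_mood"] = mid["mood_score"]
        frame["worries"] = mid["worries_score"]
        for col in ("sex", "age_group", "country", "essential_worker"):
            if col in mid.columns:
                frame[col] = mid[col]
        noise_cols = [c for c in mid.columns if c.startswith("noise_")]
        for col in noise_cols:
            frame[col] = mid[col]
        frame["subtype"] = matched_labels[mid_tp].reindex(frame.index).astype("Int64")
        for col in lc_items:
            frame[col] = mid[col]
        if "mood_followup" in last.columns:
            frame["outcome"] = last["mood_followup"].reindex(frame.index)
        else:
            frame["outcome"] = last["mood_score"].reindex(frame.index)

        oxcgrt_cols = None
        us_mask = None
        if config.oxcgrt_csv or config.simulate_oxcgrt_series:
            series = (
                load_series(config.oxcgrt_csv)
                if config.oxcgrt_csv
                else simulate_oxcgrt(seed=seeds[4])
            )
            means = window_average(series, *OXCGRT_WINDOW)
            cov = mid[["state", "country"]].copy()
            joined = join_indices(cov, means)
            for col in INDEX_COLS:
                frame[col] = joined[col]
            oxcgrt_cols = INDEX_COLS
            us_mask = mid["country"] == "US"

        base = [c for c in BASE_PREDICTORS if c in frame.columns] + noise_cols
        cats = [c for c in CATEGORICAL_PREDICTORS if c in frame.columns]
        variants = build_model_variants(
            frame.assign(subtype=frame["subtype"].astype(float)),
            outcome="outcome",
            base_predictors=base,
            subtype_col="subtype",
            item_cols=lc_items,
            oxcgrt_cols=oxcgrt_cols,
            us_mask=us_mask,
            categorical=cats,
        )
        forest_accounting = {}
        model_summary = {}
        for name, table in variants.items():
            model = fit_forest(table, params=config.forest_params, seed=seeds[2])
            r2 = oob_r2(model, table)
            imp = conditional_importance(
                model, table,
                assoc_threshold=config.assoc_threshold,
                n_permutations=config.n_permutations,
                seed=seeds[3],
            )
            imp.to_frame().to_csv(outdir / f"importance_{name}.csv", index=False)
            manifest["files"].append(f"importance_{name}.csv")
            forest_accounting[name] = {
                "input_n": table.n_rows + table.n_dropped,
                "analyzed_n": table.n_rows,
                "deleted_n": table.n_dropped,
            }
            model_summary[name] = {
                "oob_r2": r2,
                "n_rows": table.n_rows,
                "n_predictors": table.n_features,
                "hyperparameters": {
                    k: v for k, v in model.params.items()
                },
                "seed": model.seed,
                "top_predictors": imp.to_frame()["feature"].head(5).tolist(),
            }
        manifest["stages"]["forest"] = forest_accounting
        manifest["oob_r2"] = {k: v["oob_r2"] for k, v in model_summary.items()}
        (outdir / "model_summary.json").write_text(json.dumps(model_summary, indent=2))
        manifest["files"].append("model_summary.json")
        if truth is not None:
            manifest["r2_generating"] = truth.r2_generating

        manifest["files"] = sorted(manifest["files"])
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
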