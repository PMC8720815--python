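# lifechange

Heterogeneity analysis of multi-wave pandemic surveys: who experienced which
kind of life-change stress, how stable those experiences were over time, and
what best predicted mood months later.

The package implements a three-stage pipeline for longitudinal survey cohorts
(adults or parent-reported children) measured at three waves with a 14-item
pandemic life-change battery, a 10-item circumplex mood battery and a 6-item
COVID-worries battery:

1. **Subtyping** — participants are clustered into *life-change-stress
   subtypes* by Louvain community detection on the graph whose edge weights
   are Pearson correlations between participants' z-scored item vectors
   (negative correlations truncated to zero). Louvain maximises modularity

   `Q = (1/2m) Σᵢⱼ [Aᵢⱼ − γ kᵢkⱼ/2m] δ(cᵢ, cⱼ)`

   and is stabilised by **bootstrap aggregation**: the cohort is resampled
   with replacement B times, each resample is re-clustered, and the fraction
   of resamples in which two participants land in the same community (among
   resamples containing both) forms a consensus co-assignment matrix S; the
   final subtypes are a Louvain partition of S. Subtypes are named from their
   social vs economic mean loadings (e.g. "Higher Social/Higher Economic")
   and matched across waves by optimal profile correlation.

2. **Transitions** — matched subtype labels at consecutive waves are
   cross-tabulated; for every transition path the within-person change in
   mood and worries scores is tested with a paired t-test and starred at
   p < .05 / .01 / .001.

3. **Prediction** — a regression forest with reduced-bias split selection
   (split variable chosen by strongest association with the node outcome,
   trees grown on balanced bootstraps) predicts follow-up mood from mid-wave
   predictors, and ranks them by **conditional permutation importance**: a
   predictor's out-of-bag values are permuted within strata defined by
   correlated covariates' split points, isolating its contribution given its
   correlates. Three model variants: subtype as one predictor (A), the 14
   items in its place (B), and A plus regional policy/threat index averages
   on US rows (C).

Because raw survey data of this kind are not publicly depositable, the
package ships a first-class synthetic-cohort generator with planted ground
truth (subtype labels, Markov transition matrix, outcome coefficients and
generating R²), so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` walk through the full study on a
simulated 600-participant cohort (3 planted subtypes, 80% wave-to-wave stay
probability, 2% item missingness):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_score_scales.py
python analysis/03_derive_subtypes.py
python analysis/04_track_transitions.py
python analysis/05_rank_predictors.py
```

Script 03 recovers the planted structure at every wave:

```
may: n=457 complete, K=3, ARI vs planted = 0.929
  subtype 1 (Intermediate Social/Lower Economic): n=169
  subtype 2 (Lower Social/Higher Economic): n=145
  subtype 3 (Higher Social/Higher Economic): n=143
```

K=3 is the planted number of subtypes; the adjusted Rand index (ARI) of
0.93 against the planted labels means assignments are nearly exact, and the
matched cross-wave profile correlations (≥ 0.98) confirm the same structure
re-emerges independently at each wave. Script 04 then reports

```
april -> may: 344 completers, 259 stable (0.75; planted stay prob 0.80)
significant per-path changes:
 from_subtype  to_subtype   score  n  estimate     p stars
            0           1    mood 11     0.436 0.007    **
```

— observed stability (0.75) sits just below the planted stay probability
(0.80) because a small fraction of labels are misassigned, and moving into a
higher-stress subtype is accompanied by a significant within-person mood
increase. Script 05 fits the forest variants:

```
variant A: n=339, p=12, OOB R^2 = 0.310
   feature  conditional_importance  marginal_importance  rank
prior_mood                  0.1151               0.1163     1
   worries                  0.0420               0.0419     2
   subtype                  0.0261               0.0254     3
```

The three predictors that actually drive the simulated outcome (prior mood,
worries, subtype) occupy the top three conditional-importance ranks, ahead
of all five pure-noise predictors.

A `lifechange` console script exposes the same pipeline
(`lifechange run-all --simulate --seed 1 --outdir results/run`, plus
`simulate`, `score`, `subtype`, `transitions`, `predict` and `report`
subcommands).

## Layout

- `src/lifechange/` — library: codebook/datasets, synthetic generator,
  scoring, similarity graph + Louvain, bagged subtyping, longitudinal
  statistics, conditional forest, policy-index handling, pipeline, CLI.
- `analysis/` — numbered narrative drivers (the worked example above).
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and known limitations.
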