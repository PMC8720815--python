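# Methods

This note documents the models and procedures implemented in `lifechange`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-cohort experiments do and do not demonstrate.

## Study design emulated

Three survey waves (labelled april, may, november) of one cohort. Each wave
measures 14 ordinal life-change items (7 social/interpersonal, 7 economic,
all 1–5, some reverse-keyed), 10 circumplex mood items and 6 COVID-worries
items (1–5, averaged into scale scores after recoding), plus demographics,
an optional US state code, and impact indicators. Missing responses are
handled by **model-wise deletion** throughout: a participant is dropped from
a given analysis stage exactly when any variable that stage needs is
missing, and each stage's manifest entry reports
`input_n = analyzed_n + deleted_n`.

## Scale scoring

Reverse-keyed items are reflected (`x → min + max − x`); a battery score is
the arithmetic mean of its recoded items, missing whenever any item is
missing. Prorated means are deliberately not offered — the deletion policy
is part of the design. As a lightweight unidimensionality check the package
reports Cronbach's alpha and the first-eigenvalue fraction of the item
correlation matrix; this replaces a full confirmatory factor analysis,
which is out of scope.

## Subtyping

**Similarity.** Items are z-scored per column; the participant graph has
edge weights `max(0, r_ij)` where `r_ij` is the Pearson correlation between
participants i and j's item vectors. Negative truncation keeps weights
compatible with classic modularity, which assumes non-negative edges.
Participants whose item vector is constant (correlation undefined) are
excluded with a warning. Note the important consequence of this choice:
row-wise correlation is invariant to a constant shift of a participant's
profile, so subtypes are *patterns* of stress, not *levels* — two groups
differing only in overall severity are indistinguishable by construction.

**Louvain.** Standard two-phase heuristic (greedy local moves, then
aggregation, repeated to fixation) maximising modularity with resolution
γ (default 1.0). Node visit order is shuffled by the seed; the returned Q
is recomputed from the final labels and never decreases across passes.
Aggregated matrices use the congruence convention `A' = OᵀAO`, which makes
coarse-level modularity exactly equal to the induced fine-level modularity.
On graphs small enough to enumerate all set partitions (≤ 8 nodes) the
heuristic lands within 0.05 of the exhaustive optimum (tested on random
weighted graphs).

**Bagging.** B bootstrap resamples (default B = 100) of participants with
replacement; each resample's unique participants are re-clustered from
scratch (including re-z-scoring within the resample). The co-assignment
matrix S holds, per pair, the fraction of resamples containing both in
which they were co-clustered; pairs never co-sampled get S = 0 and a
coverage warning is emitted when any pair was co-sampled in fewer than
30% of resamples (at B = 100 a small tail of pairs always sits near that
line — the warning is informational). Final subtypes are a Louvain
partition of S itself, keeping a single clustering paradigm; hierarchical
consensus clustering was considered and rejected for that reason.
Communities smaller than 5% of n are merged into the larger subtype whose
profile they correlate with most (logged, and can be disabled) — small
splinter communities are rarely interpretable at survey scale.

**Naming and matching.** Subtype profiles are per-subtype means of the
z-scored items. Within each domain (social, economic) profiles are ranked;
extremes are "Lower"/"Higher" and a middle subtype is "Intermediate" only
when it sits more than 0.1 z-units from both extremes, otherwise it takes
the nearer label; exact ties fall back to subtype-index order with a
warning. Solutions from different waves (or cohorts) are matched by
maximising total Pearson correlation between profile pairs (Hungarian
assignment); labels are then mapped onto the reference wave's identity,
and a wave subtype with no reference counterpart keeps a new id with a
warning rather than being silently renumbered.

## Transitions

Matched labels at consecutive waves are cross-tabulated over participants
present (and subtyped) at both; counts always sum to the completer n. Per
transition path the within-person change in a scale score is tested with a
paired t-test (two-sided; the t statistic is computed directly and the
p-value comes from the t distribution); paths with one member are reported
without a test, and zero-variance differences are flagged rather than
tested. Significance stars follow the conventional * p<.05, ** p<.01,
*** p<.001 mapping on raw p-values; a Benjamini–Hochberg option exists but
is off by default to match the starred-raw-p reporting convention. Group
comparisons across subtypes use one-way ANOVA (groups with fewer than two
observations excluded with a warning) and Pearson chi-square without
continuity correction.

## Conditional random forest

A regression forest designed to approximate conditional-inference forests
without their permutation-test machinery:

- **Split selection.** At each node, `mtry` candidate predictors are drawn;
  the split *variable* is the candidate with the largest absolute
  association with the node outcome (|Pearson r| for numeric, √(η²) from a
  one-way ANOVA for categorical — both on a common 0–1 scale), which
  removes most of CART's bias toward many-valued predictors. Only then is
  the best cutpoint (numeric) or binary level-set split (categorical,
  levels ordered by node outcome mean — exact for squared error) found by
  variance reduction. If the selected variable admits no valid split the
  remaining candidates are tried in descending association order before
  the node becomes a leaf.
- **Balanced bootstrap.** In-bag indices are dealt without replacement from
  a replicated index pool in which per-row counts differ by at most one, so
  every row appears (almost) equally often across the ensemble; per-tree
  in-bag fraction 0.632. Out-of-bag (OOB) rows give honest error:
  `R² = 1 − Σ(y − ŷ_OOB)²/Σ(y − ȳ)²` with ŷ_OOB averaging only trees for
  which the row is out-of-bag.
- **Importance.** For predictor j, the conditioning set Z contains every
  predictor whose association with j exceeds a threshold (default 0.2;
  |r| for numeric pairs, Cramér's V when a categorical is involved, with
  numerics quartile-binned for that purpose). Per tree, j's OOB values are
  permuted within the cells of a grid built from that tree's own split
  points on Z (numeric cutpoints; level-set indicators for categoricals),
  over `n_permutations` rounds; importance is the mean over trees of the
  permuted-minus-original OOB mean squared error. Marginal importance uses
  one global cell. Negative values are reported as-is; any "importance > 0
  only" filtering is a display decision left to report rendering.
- **Defaults.** `n_trees = 500`, `mtry = ⌈√p⌉`, `min_node_size = 5`,
  `assoc_threshold = 0.2`, `n_permutations = 5`, all configurable. The
  analysis scripts and end-to-end tests run 100–150 trees with 3
  permutation rounds — for this problem size (≈ 8–25 predictors, n ≤ 1000)
  importance rankings are already stable there, and those are the
  package's standard analysis settings.
- **Invariances.** Columns are canonicalised by feature name before
  fitting, so fits are invariant to predictor column order; categorical
  splits depend only on outcome means per level, so renaming levels does
  not change predictions. All randomness flows from the single seed.

One caveat documented from measurement: permutation importance under
*exact* predictor duplication is mildly subadditive — each copy carries
roughly half the lone predictor's importance, but their sum lands ~15–20%
below it, because the intact copy keeps compensating at splits the
permutation does not touch. The test suite asserts the band that actually
holds rather than exact additivity.

Model variants: **A** uses the derived subtype as one categorical
predictor alongside prior mood, worries, demographics and impact
indicators; **B** replaces the subtype with its 14 constituent items;
**C** restricts to US rows and adds four regional policy/threat indices,
each averaged per state over April 1 – May 31, 2020 (inclusive) and
left-joined on the state code — non-US rows get missing indices by design
and drop out of that variant under model-wise deletion.

## Synthetic-cohort generator

The generator is the package's study-conditions definition, not a test
fixture:

- **Subtypes.** Wave-1 labels are drawn from configured prevalences
  (uniform by default); later waves follow a row-stochastic transition
  matrix (default: 0.8 stay, remainder spread evenly).
- **Profiles.** Default profiles combine block means on the social and
  economic item sets (low/low, high/high, mixed; block separation 1.0
  z-unit, i.e. blocks at ±0.5) with deterministic item-level "texture":
  mutually orthogonal ±1 Walsh patterns scaled by an amplitude equal to
  the block separation. The texture exists because the correlation
  similarity is blind to pure level shifts (see Subtyping above): with
  flat block profiles, low/low and high/high subtypes are provably
  indistinguishable at any separation. The chosen amplitude makes
  within-block item variation comparable to the between-block contrast —
  the way empirical stress-profile plots look — and sets the generator's
  difficulty scale so that recovery is essentially perfect at 2 z-units
  of separation and reliable but not error-free at 1 z-unit.
- **Items.** Ordinal responses discretise latent Gaussians (profile mean +
  unit noise) at equally spaced cutpoints spanning ±2 SD. Mood and worries
  items share a per-participant latent severity that follows an AR(1)
  across waves (ρ = 0.6).
- **Outcome.** Follow-up mood = intercept + β₁·(mid-wave mood score) +
  β₂·(mid-wave worries score) + reference-coded subtype effect + Gaussian
  noise, clipped into [1, 5] (clipping affects < 1% of values at the
  defaults and a warning fires if it exceeds 5%). `r2_generating` is the
  signal fraction of pre-clipping outcome variance computed from the
  simulated predictors; setting `outcome_target_r2` solves for the noise
  SD that achieves an exact target. Noise predictors are standard normal
  and independent of everything.
- **Missingness.** MCAR only, item cells replaced independently at the
  configured rate; covariates untouched. MAR/MNAR are out of scope because
  the deletion policy under study does not distinguish them.

What the synthetic experiments show: that the pipeline recovers planted
block-structured subtypes, their Markov dynamics and a planted outcome
model under realistic measurement (ordinal discretisation, missingness,
estimated rather than true labels). What they do not show: robustness to
non-block stress structure, informative missingness, attrition that
depends on stress, or item distributions of any particular real cohort —
the generator's distributions are declared assumptions, not estimates of
real survey data.

## Numerical and design details

- All stochastic stages derive their streams from one master seed
  (`numpy.random.SeedSequence` spawning); repeated runs are bit-identical,
  which the test suite and acceptance script verify on full output
  bundles.
- Louvain move gains use a 1e-12 tolerance to prevent tie oscillation; the
  "Intermediate" naming gap uses a 1e-9 tolerance so a gap of exactly 0.1
  does not flip on float representation.
- The modularity of a partition stored on a `Partition` object always
  matches recomputation from its labels to 1e-9 (tested).
- Degenerate inputs error loudly with the offending entity named: invalid
  transition rows, empty or all-zero similarity graphs, constant outcomes,
  batteries with missing items, out-of-range responses.
- The pipeline writes a FAILED marker naming the failing stage and keeps
  partial outputs when any stage raises.

## Known limitations

- Modularity-based clustering with γ = 1 has a resolution limit; very
  small genuine subtypes may be absorbed (and the explicit small-community
  merge would do so deliberately below 5% of n).
- The forest's association-based split selection reduces but does not
  eliminate selection bias, and conditional importance is computed from
  per-tree grids, which can be coarse for shallow trees.
- Scale scores treat ordinal items as interval; this matches the averaging
  convention the design specifies but is an approximation.
- The policy-index join assumes state-level series for US participants
  only; other regional schemes would need a different region column.
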