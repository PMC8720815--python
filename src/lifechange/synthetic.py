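"""Synthetic survey cohorts with planted subtype structure and outcomes.

The generator emulates a three-wave pandemic survey: participants belong to
latent life-change-stress subtypes that evolve between waves under a Markov
transition matrix; ordinal Likert items are produced by thresholding latent
Gaussians; a follow-up mood outcome follows a linear model in the mid-wave
mood score, worries score and subtype.  Everything needed to verify recovery
(labels, profiles, coefficients, generating R-squared) is returned as a
:class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import ItemCodebook, default_codebook
from .datasets import ID_COL, TIME_COL, SurveyDataset

DEFAULT_TIMEPOINTS = ["april", "may", "november"]
US_STATES = ["NY", "CA", "TX", "FL", "IL", "PA", "OH", "WA"]

# Subtype block pattern on (social, economic) domains: low/low, high/high,
# then mixed blocks for any further subtypes.
_BLOCK_PATTERNS = [(-1, -1), (+1, +1), (-1, +1), (+1, -1)]


def make_profiles(
    n_subtypes: int = 3,
    separation: float = 1.0,
    n_social: int = 7,
    n_economic: int = 7,
    texture: float | None = None,
) -> np.ndarray:
    """Latent item means (subtype x item, z-scale) with block structure.

    Social items come first.  ``separation`` is the z-unit distance between
    the low and high block means (i.e. blocks sit at +/- separation/2).

    On top of the block means each subtype carries a deterministic
    item-level "texture" — mutually orthogonal +/- patterns (Walsh
    functions) of amplitude ``texture`` (default: equal to ``separation``)
    — because real item batteries never have literally identical means
    across items, and a participant-correlation similarity cannot
    distinguish subtypes whose profiles differ only by a constant level
    shift (row-centering removes it).  The default amplitude makes the
    within-block item variation comparable to the between-block contrast,
    matching how empirical stress-profile plots look, and calibrates the
    generator's difficulty scale so that subtype recovery is essentially
    perfect at 2 z-units of block separation and reliable (though not
    error-free) at 1 z-unit.  Block means stay within texture/7 of the
    nominal +/- separation/2 (exactly there when the pattern tiles
    evenly).
    """
    from scipy.linalg import hadamard

    if texture is None:
        texture = separation
    n_items = n_social + n_economic
    half = separation / 2.0
    H = hadamard(8)  # rows 1.. are zero-mean orthogonal +/- patterns
    if n_subtypes > 7:
        raise ValueError("at most 7 subtypes supported by the texture patterns")
    rows = []
    for k in range(n_subtypes):
        s_sign, e_sign = _BLOCK_PATTERNS[k % len(_BLOCK_PATTERNS)]
        base = np.array([s_sign * half] * n_social + [e_sign * half] * n_economic)
        pattern = H[k + 1, np.arange(n_items) % 8]
        rows.append(base + texture * pattern)
    return np.asarray(rows, dtype=float)


def _default_transition(n_subtypes: int, stay: float = 0.8) -> np.ndarray:
    off = (1.0 - stay) / max(n_subtypes - 1, 1)
    mat = np.full((n_subtypes, n_subtypes), off)
    np.fill_diagonal(mat, stay if n_subtypes > 1 else 1.0)
    return mat


def _default_outcome_coefs(n_subtypes: int) -> dict:
    effects = [0.0] + [0.35 - 0.15 * i for i in range(n_subtypes - 1)]
    return {
        "intercept": 0.6,
        "beta_prior_mood": 0.5,
        "beta_worries": 0.3,
        "subtype_effects": effects,
        "noise_sd": 0.45,
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    The transition matrix must be row-stochastic; ``subtype_effects`` is
    reference-coded (exactly one zero entry).  ``outcome_target_r2``, when
    set, overrides ``noise_sd`` by solving for the residual SD that makes
    the signal fraction of outcome variance equal the target.
    """

    n_participants: int = 600
    n_subtypes: int = 3
    item_codebook: ItemCodebook = field(default_factory=default_codebook)
    subtype_profiles: np.ndarray | None = None
    timepoints: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    transition_matrix: np.ndarray | None = None
    prevalences: np.ndarray | None = None
    outcome_coefs: dict | None = None
    outcome_target_r2: float | None = None
    n_noise_predictors: int = 0
    missing_rate: float = 0.0
    item_noise_sd: float = 1.0
    severity_ar: float = 0.6
    us_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_subtypes
        if self.subtype_profiles is None:
            n_soc = len(self.item_codebook.domain_items("social"))
            n_eco = len(self.item_codebook.domain_items("economic"))
            self.subtype_profiles = make_profiles(k, 1.0, n_soc, n_eco)
        self.subtype_profiles = np.asarray(self.subtype_profiles, dtype=float)
        if self.transition_matrix is None:
            self.transition_matrix = _default_transition(k)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        rowsums = self.transition_matrix.sum(axis=1)
        bad = np.nonzero(np.abs(rowsums - 1.0) > 1e-9)[0]
        if self.transition_matrix.shape != (k, k) or bad.size:
            row = int(bad[0]) if bad.size else -1
            raise ValueError(
                f"transition_matrix must be {k}x{k} row-stochastic; "
                f"row {row} sums to {rowsums[row] if row >= 0 else 'n/a'}"
            )
        if self.prevalences is None:
            self.prevalences = np.full(k, 1.0 / k)
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        if abs(self.prevalences.sum() - 1.0) > 1e-9 or (self.prevalences < 0).any():
            raise ValueError("prevalences must be a probability vector")
        if self.outcome_coefs is None:
            self.outcome_coefs = _default_outcome_coefs(k)
        effects = np.asarray(self.outcome_coefs["subtype_effects"], dtype=float)
        if effects.size != k or int(np.sum(effects == 0.0)) != 1:
            raise ValueError(
                "subtype_effects must have one entry per subtype with exactly "
                "one zero reference entry"
            )
        if self.outcome_coefs["noise_sd"] < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.outcome_target_r2 is not None and not (0.0 < self.outcome_target_r2 < 1.0):
            raise ValueError("outcome_target_r2 must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated cohort."""

    labels: pd.DataFrame          # participant_id x timepoint -> subtype id
    profiles: np.ndarray          # generating subtype x item latent means
    outcome_coefs: dict           # with noise_sd resolved to its final value
    r2_generating: float          # signal fraction of outcome variance

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": {
                tp: self.labels[tp].tolist() for tp in self.labels.columns
            },
            "participant_ids": self.labels.index.tolist(),
            "profiles": self.profiles.tolist(),
            "outcome_coefs": {
                key: (list(val) if isinstance(val, (list, tuple, np.ndarray)) else val)
                for key, val in self.outcome_coefs.items()
            },
            "r2_generating": self.r2_generating,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _discretize(z: np.ndarray, smin: int, smax: int) -> np.ndarray:
    """Threshold latent z-values at equally spaced cutpoints spanning +/-2 SD."""
    cuts = np.linspace(-2.0, 2.0, smax - smin)
    return (smin + np.digitize(z, cuts)).astype(float)


def _markov_step(labels: np.ndarray, transition: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(transition, axis=1)[labels]
    u = rng.random(labels.size)
    return (u[:, None] > cum).sum(axis=1)


def _battery_values(
    latent: np.ndarray, items: list[str], codebook: ItemCodebook,
    noise_sd: float, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Severity-coded and raw (direction-respecting) ordinal item values.

    ``latent`` is (n,) or (n, n_items) on the z-scale.  Returns
    ``(coded, raw)`` where ``raw`` reflects reverse-keyed items so that a
    subsequent recode step restores ``coded``.
    """
    n = latent.shape[0]
    if latent.ndim == 1:
        latent = np.repeat(latent[:, None], len(items), axis=1)
    z = latent + rng.normal(0.0, noise_sd, size=(n, len(items)))
    coded = np.empty_like(z)
    raw = np.empty_like(z)
    for j, name in enumerate(items):
        item = codebook[name]
        coded[:, j] = _discretize(z[:, j], item.scale_min, item.scale_max)
        if item.direction == "reversed":
            raw[:, j] = item.scale_min + item.scale_max - coded[:, j]
        else:
            raw[:, j] = coded[:, j]
    return coded, raw


def generate_population(config: GeneratorConfig) -> tuple[SurveyDataset, SyntheticTruth]:
    """Simulate a full multi-wave cohort with planted subtypes and outcome.

    Deterministic given ``config.seed``.  The follow-up mood outcome
    (``mood_followup`` on the last wave's rows) is a linear model in the
    mid-wave mood score, worries score and subtype, plus Gaussian noise,
    clipped into [1, 5].
    """
    cb = config.item_codebook
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    k = config.n_subtypes
    tps = config.timepoints
    if len(tps) < 2:
        raise ValueError("need at least two timepoints")

    lc_items = cb.battery_items("life_change")
    mood_items = cb.battery_items("mood")
    worry_items = cb.battery_items("worries")
    if config.subtype_profiles.shape != (k, len(lc_items)):
        raise ValueError(
            f"subtype_profiles must be {k}x{len(lc_items)} "
            f"(got {config.subtype_profiles.shape})"
        )

    # --- subtype trajectories -------------------------------------------
    labels = np.empty((len(tps), n), dtype=int)
    labels[0] = rng.choice(k, size=n, p=config.prevalences)
    for t in range(1, len(tps)):
        labels[t] = _markov_step(labels[t - 1], config.transition_matrix, rng)

    # --- covariates ------------------------------------------------------
    country = np.where(rng.random(n) < config.us_fraction, "US", "UK")
    state = pd.Series(rng.choice(US_STATES, size=n)).where(country == "US")
    sex = rng.choice(["female", "male"], size=n, p=[0.55, 0.45])
    age_group = rng.choice(["18-29", "30-39", "40-49", "50+"], size=n)
    essential_worker = rng.random(n) < 0.3
    noise_cols = {
        f"noise_{j + 1:02d}": rng.normal(0.0, 1.0, size=n)
        for j in range(config.n_noise_predictors)
    }

    # --- latent mood/worry severities (AR across waves) ------------------
    rho = config.severity_ar
    sev_mood = np.empty((len(tps), n))
    sev_worry = np.empty((len(tps), n))
    sev_mood[0] = rng.normal(0.0, 1.0, n)
    sev_worry[0] = rng.normal(0.0, 1.0, n)
    for t in range(1, len(tps)):
        sev_mood[t] = rho * sev_mood[t - 1] + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        sev_worry[t] = rho * sev_worry[t - 1] + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)

    # --- per-wave item responses ----------------------------------------
    frames = []
    coded_scores: dict[str, dict[str, np.ndarray]] = {}
    for t, tp in enumerate(tps):
        lc_latent = config.subtype_profiles[labels[t]]
        _, lc_raw = _battery_values(lc_latent, lc_items, cb, config.item_noise_sd, rng)
        mood_coded, mood_raw = _battery_values(
            0.8 * sev_mood[t], mood_items, cb, 0.6, rng
        )
        worry_coded, worry_raw = _battery_values(
            0.8 * sev_worry[t], worry_items, cb, 0.6, rng
        )
        coded_scores[tp] = {
            "mood": mood_coded.mean(axis=1),
            "worries": worry_coded.mean(axis=1),
        }
        frame = pd.DataFrame({ID_COL: np.arange(n), TIME_COL: tp})
        frame["country"] = country
        frame["state"] = state
        frame["sex"] = sex
        frame["age_group"] = age_group
        frame["essential_worker"] = essential_worker.astype(int)
        for col, vals in noise_cols.items():
            frame[col] = vals
        for j, name in enumerate(lc_items):
            frame[name] = lc_raw[:, j]
        for j, name in enumerate(mood_items):
            frame[name] = mood_raw[:, j]
        for j, name in enumerate(worry_items):
            frame[name] = worry_raw[:, j]
        frames.append(frame)

    # --- follow-up outcome ----------------------------------------------
    coefs = dict(config.outcome_coefs)
    effects = np.asarray(coefs["subtype_effects"], dtype=float)
    mid_tp = tps[1]
    linpred = (
        coefs["intercept"]
        + coefs["beta_prior_mood"] * coded_scores[mid_tp]["mood"]
        + coefs["beta_worries"] * coded_scores[mid_tp]["worries"]
        + effects[labels[1]]
    )
    signal_var = float(np.var(linpred))
    noise_sd = float(coefs["noise_sd"])
    if config.outcome_target_r2 is not None:
        t2 = config.outcome_target_r2
        noise_sd = float(np.sqrt(signal_var * (1.0 - t2) / t2))
        coefs["noise_sd"] = noise_sd
    outcome = linpred + rng.normal(0.0, noise_sd, size=n)
    n_clipped = int(np.sum((outcome < 1.0) | (outcome > 5.0)))
    if n_clipped > 0.05 * n:
        warnings.warn(
            f"{n_clipped}/{n} outcomes clipped into [1, 5]; generating R2 is "
            "distorted — consider a smaller intercept or effects",
            stacklevel=2,
        )
    outcome = np.clip(outcome, 1.0, 5.0)
    frames[-1]["mood_followup"] = outcome
    denom = signal_var + noise_sd**2
    r2_gen = signal_var / denom if denom > 0 else 0.0

    data = pd.concat(frames, ignore_index=True)
    dataset = SurveyDataset(data, list(tps))
    if config.missing_rate > 0:
        dataset = inject_missingness(
            dataset, config.missing_rate,
            seed=int(np.random.default_rng(config.seed + 1).integers(2**31)),
            codebook=cb,
        )
    truth = SyntheticTruth(
        labels=pd.DataFrame(labels.T, index=pd.RangeIndex(n, name=ID_COL), columns=tps),
        profiles=config.subtype_profiles.copy(),
        outcome_coefs=coefs,
        r2_generating=float(r2_gen),
    )
    return dataset, truth


def inject_missingness(
    dataset: SurveyDataset,
    rate: float,
    seed: int,
    codebook: ItemCodebook | None = None,
) -> SurveyDataset:
    """Replace item responses by NaN independently with probability ``rate``.

    Missingness is completely at random (MCAR) and touches item columns
    only; covariates and the outcome are left intact.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    out = dataset.copy()
    if rate == 0.0:
        return out
    cb = codebook or default_codebook()
    item_cols = out.item_columns(cb)
    rng = np.random.default_rng(seed)
    block = out.data[item_cols].to_numpy(float)
    mask = rng.random(block.shape) < rate
    block[mask] = np.nan
    out.data[item_cols] = block
    return out


def simulate_oxcgrt(
    states: list[str] | None = None,
    start: str = "2020-04-01",
    end: str = "2020-05-31",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic daily state-level policy/threat index series.

    Emulates the shape of public government-response tracker exports: one
    row per (region, date) with containment/health and economic-support
    indices (0-100) and cumulative case/death rates per million.
    """
    states = states or US_STATES
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, end, freq="D")
    rows = []
    for region in states:
        base_cont = rng.uniform(50, 85)
        base_econ = rng.uniform(30, 70)
        case_rate = rng.uniform(50, 400)
        death_rate = case_rate * rng.uniform(0.01, 0.04)
        cases = np.cumsum(rng.gamma(2.0, case_rate / 2.0, size=len(dates)))
        deaths = np.cumsum(rng.gamma(2.0, death_rate / 2.0, size=len(dates)))
        for i, date in enumerate(dates):
            rows.append(
                {
                    "region": region,
                    "date": date.strftime("%Y-%m-%d"),
                    "containment_health_index": float(
                        np.clip(base_cont + rng.normal(0, 3), 0, 100)
                    ),
                    "economic_support_index": float(
                        np.clip(base_econ + rng.normal(0, 3), 0, 100)
                    ),
                    "confirmed_cases_per_million": float(cases[i]),
                    "confirmed_deaths_per_million": float(deaths[i]),
                }
            )
    return pd.DataFrame(rows)
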