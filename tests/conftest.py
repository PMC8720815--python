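"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import warnings

import pytest

import lifechange as lc


@pytest.fixture(scope="session")
def codebook():
    return lc.default_codebook()


@pytest.fixture(scope="session")
def small_cohort():
    """300-participant cohort with 3 planted subtypes and 3 noise predictors."""
    cfg = lc.GeneratorConfig(n_participants=300, n_noise_predictors=3, seed=42)
    dataset, truth = lc.generate_population(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def scored_cohort(small_cohort, codebook):
    dataset, truth, cfg = small_cohort
    return lc.attach_scores(dataset, codebook), truth


@pytest.fixture(scope="session")
def may_solution(scored_cohort, codebook):
    """Bagged subtype solution for the mid wave of the small cohort."""
    scored, _ = scored_cohort
    mat = scored.item_matrix("may", codebook.battery_items("life_change"),
                             complete_only=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lc.bagged_louvain(mat, n_bootstraps=40, seed=7, codebook=codebook)
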