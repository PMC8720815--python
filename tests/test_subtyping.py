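"""Bagged consensus subtyping, subtype naming and cross-solution matching."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import lifechange as lc
from lifechange.subtyping import _merge_small_communities, _relabel_by_size
from lifechange.synthetic import make_profiles


def _planted_matrix(n, n_subtypes, separation, seed, codebook):
    prof = make_profiles(n_subtypes, separation)
    cfg = lc.GeneratorConfig(
        n_participants=n, n_subtypes=n_subtypes, subtype_profiles=prof, seed=seed
    )
    dataset, truth = lc.generate_population(cfg)
    scored = lc.attach_scores(dataset, codebook)
    mat = scored.item_matrix("may", codebook.battery_items("life_change"),
                             complete_only=True)
    return mat, truth.labels["may"]


class TestBaggedLouvain:
    def test_coassignment_invariants(self, may_solution):
        S = may_solution.coassignment
        assert np.array_equal(S, S.T)
        assert np.allclose(np.diagonal(S), 1.0)
        assert S.min() >= 0.0 and S.max() <= 1.0

    def test_single_bootstrap_gives_binary_consistent_consensus(self, codebook):
        mat, _ = _planted_matrix(80, 2, 2.0, seed=0, codebook=codebook)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = lc.bagged_louvain(mat, n_bootstraps=1, seed=3, codebook=codebook)
        S = sol.coassignment.copy()
        np.fill_diagonal(S, np.nan)
        observed = S[np.isfinite(S) & (S > 0)]
        assert np.isin(np.unique(np.round(observed, 12)), [0.0, 1.0]).all()
        # co-clustering from one partition is transitive on co-sampled triples
        ones = S == 1.0
        n = S.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.choice(n, 3, replace=False)
            if ones[i, j] and ones[j, k]:
                assert S[i, k] in (0.0, 1.0)
                if S[i, k] == 0.0:
                    # only allowed when i,k were never co-sampled together
                    assert not ones[i, k]

    def test_two_planted_subtypes_recovered_exactly(self, codebook):
        mat, planted = _planted_matrix(200, 2, 2.0, seed=1, codebook=codebook)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = lc.bagged_louvain(mat, n_bootstraps=50, seed=11, codebook=codebook)
        ari = adjusted_rand_score(planted.loc[sol.labels.index], sol.labels)
        assert ari == pytest.approx(1.0)

    def test_run_is_seed_deterministic(self, codebook):
        mat, _ = _planted_matrix(60, 2, 2.0, seed=2, codebook=codebook)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = lc.bagged_louvain(mat, n_bootstraps=10, seed=5, codebook=codebook)
            b = lc.bagged_louvain(mat, n_bootstraps=10, seed=5, codebook=codebook)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.coassignment, b.coassignment)

    def test_profiles_are_per_subtype_z_means(self, may_solution):
        assert may_solution.profiles.shape[0] == may_solution.n_subtypes
        # z-scored item means weighted by subtype size must average to ~0
        sizes = may_solution.labels.value_counts().sort_index().to_numpy()
        weighted = (may_solution.profiles.to_numpy() * sizes[:, None]).sum(0) / sizes.sum()
        assert np.allclose(weighted, 0.0, atol=1e-9)

    def test_contract_errors(self, codebook):
        mat, _ = _planted_matrix(60, 2, 2.0, seed=3, codebook=codebook)
        with pytest.raises(ValueError):
            lc.bagged_louvain(mat, n_bootstraps=0)
        with pytest.raises(ValueError):
            lc.bagged_louvain(mat.iloc[:5], n_bootstraps=5)


class TestSmallCommunityMerge:
    def test_small_cluster_absorbed_by_most_similar(self):
        rng = np.random.default_rng(4)
        Z = np.vstack(
            [
                rng.normal(0, 0.1, (40, 6)) + np.array([1, 1, 1, -1, -1, -1.0]),
                rng.normal(0, 0.1, (40, 6)) + np.array([-1, -1, -1, 1, 1, 1.0]),
                rng.normal(0, 0.1, (3, 6)) + np.array([1, 1, 1, -1, -1, -1.0]),
            ]
        )
        labels = np.array([0] * 40 + [1] * 40 + [2] * 3)
        merged, log = _merge_small_communities(Z, labels, min_frac=0.05)
        assert len(log) == 1
        assert len(np.unique(merged)) == 2
        assert (merged[80:] == merged[0]).all()  # joined the correlated cluster

    def test_relabel_by_size_is_descending(self):
        labels = np.array([2, 2, 2, 0, 0, 1])
        out = _relabel_by_size(labels)
        assert (out == np.array([0, 0, 0, 1, 1, 2])).all()


class TestNaming:
    def test_reference_profile_pattern(self, codebook):
        soc = codebook.domain_items("social")
        eco = codebook.domain_items("economic")
        prof = pd.DataFrame(
            [
                {**{c: -0.5 for c in soc}, **{c: -0.5 for c in eco}},
                {**{c: +0.6 for c in soc}, **{c: +0.7 for c in eco}},
                {**{c: -0.4 for c in soc}, **{c: +0.5 for c in eco}},
            ]
        )
        names = lc.name_subtypes(prof, codebook)
        assert names[0] == "Lower Social/Lower Economic"
        assert names[1] == "Higher Social/Higher Economic"
        assert names[2].startswith("Lower Social/")

    def test_intermediate_requires_separation(self, codebook):
        soc = codebook.domain_items("social")
        eco = codebook.domain_items("economic")
        prof = pd.DataFrame(
            [
                {**{c: -0.5 for c in soc}, **{c: -0.5 for c in eco}},
                {**{c: 0.0 for c in soc}, **{c: -0.45 for c in eco}},
                {**{c: +0.5 for c in soc}, **{c: +0.5 for c in eco}},
            ]
        )
        names = lc.name_subtypes(prof, codebook)
        assert names[1] == "Intermediate Social/Lower Economic"

    def test_tie_broken_by_index_with_warning(self, codebook):
        items = codebook.domain_items("social") + codebook.domain_items("economic")
        prof = pd.DataFrame([{c: 0.2 for c in items}] * 2)
        with pytest.warns(UserWarning, match="identical"):
            names = lc.name_subtypes(prof, codebook)
        assert names[0].startswith("Lower") and names[1].startswith("Higher")

    def test_single_subtype_named_by_sign(self, codebook):
        soc = codebook.domain_items("social")
        eco = codebook.domain_items("economic")
        prof = pd.DataFrame([{**{c: -0.3 for c in soc}, **{c: 0.4 for c in eco}}])
        assert lc.name_subtypes(prof, codebook) == ["Lower Social/Higher Economic"]

    def test_requires_both_domains(self):
        cb = lc.ItemCodebook(
            [lc.Item(f"s{i}", 1, 5, "normal", "life_change", "social") for i in range(3)]
        )
        prof = pd.DataFrame([{f"s{i}": 0.1 for i in range(3)}])
        with pytest.raises(ValueError, match="economic"):
            lc.name_subtypes(prof, cb)


class TestMatching:
    def test_self_match_is_identity(self, may_solution):
        match = lc.match_subtypes(may_solution, may_solution)
        assert match.assignment == {k: k for k in range(may_solution.n_subtypes)}
        assert all(c == pytest.approx(1.0) for c in match.matched_correlations.values())

    def test_permuted_solution_recovered(self, may_solution):
        perm = np.roll(np.arange(may_solution.n_subtypes), 1)
        permuted = may_solution.profiles.iloc[perm].reset_index(drop=True)
        match = lc.match_subtypes(permuted, may_solution.profiles)
        assert match.assignment == {i: int(perm[i]) for i in range(len(perm))}

    def test_assignment_equals_exhaustive_search(self):
        rng = np.random.default_rng(12)
        a = pd.DataFrame(rng.normal(size=(3, 8)), columns=[f"i{j}" for j in range(8)])
        b = pd.DataFrame(rng.normal(size=(3, 8)), columns=[f"i{j}" for j in range(8)])
        match = lc.match_subtypes(a, b)
        corr = match.correlation_matrix.to_numpy()
        best = max(
            sum(corr[i, p[i]] for i in range(3))
            for p in itertools.permutations(range(3))
        )
        total = sum(match.matched_correlations.values())
        assert total == pytest.approx(best, abs=1e-12)

    def test_differing_item_sets_rejected(self, may_solution):
        other = may_solution.profiles.rename(columns={"lc_family_change": "x"})
        with pytest.raises(ValueError, match="item set"):
            lc.match_subtypes(may_solution.profiles, other)
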