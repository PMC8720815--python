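"""Balanced-bootstrap regression forest and permutation importance."""

import numpy as np
import pandas as pd
import pytest

import lifechange as lc
from lifechange.forest import (
    ForestModel,
    PredictorTable,
    _Tree,
    predict,
    predictor_association_matrix,
)


def _linear_frame(seed, n=200, noise=0.5, n_noise=2):
    rng = np.random.default_rng(seed)
    cols = {"x1": rng.normal(0, 1, n)}
    for j in range(n_noise):
        cols[f"z{j}"] = rng.normal(0, 1, n)
    cols["y"] = cols["x1"] + noise * rng.normal(0, 1, n)
    return pd.DataFrame(cols)


class TestPredictorTable:
    def test_model_wise_deletion_accounting(self):
        frame = pd.DataFrame(
            {"x": [1.0, np.nan, 3.0, 4.0], "g": ["a", "b", "a", None],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        table = PredictorTable.from_frame(frame, "y")
        assert table.n_rows == 2 and table.n_dropped == 2
        assert table.categories["g"] == ["a"]

    def test_missing_outcome_column_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            PredictorTable.from_frame(pd.DataFrame({"x": [1.0]}), "y")


class TestFitForest:
    def test_noiseless_single_predictor_recovery(self):
        frame = _linear_frame(0, n=200, noise=0.0, n_noise=0)
        table = PredictorTable.from_frame(frame, "y")
        model = lc.fit_forest(table, {"n_trees": 60, "min_node_size": 2, "mtry": 1}, seed=1)
        r2 = lc.oob_r2(model, table)
        assert r2 >= 0.9

    def test_null_outcome_gives_no_skill(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame(
                {"x1": rng.normal(size=120), "x2": rng.normal(size=120),
                 "y": rng.normal(size=120)}
            )
            table = PredictorTable.from_frame(frame, "y")
            model = lc.fit_forest(table, {"n_trees": 50}, seed=seed)
            r2s.append(lc.oob_r2(model, table))
        assert np.mean(r2s) <= 0.05

    def test_oob_error_improves_with_ensemble_size(self):
        deltas = []
        for seed in range(10):
            frame = _linear_frame(seed, n=150)
            table = PredictorTable.from_frame(frame, "y")
            mses = []
            for n_trees in (1, 200):
                model = lc.fit_forest(table, {"n_trees": n_trees}, seed=seed)
                from lifechange.forest import oob_predictions
                preds, counts = oob_predictions(model, table)
                ok = counts > 0
                mses.append(np.mean((preds[ok] - table.y[ok]) ** 2))
            deltas.append(mses[0] - mses[1])
        assert np.mean(deltas) > 0  # bigger ensemble, lower OOB error on average

    def test_balanced_bootstrap_counts(self):
        frame = _linear_frame(3, n=100)
        table = PredictorTable.from_frame(frame, "y")
        model = lc.fit_forest(table, {"n_trees": 40}, seed=2)
        counts = np.zeros(table.n_rows, dtype=int)
        for bag, oob in zip(model.in_bag, model.oob):
            np.add.at(counts, bag, 1)
            assert np.intersect1d(bag, oob).size == 0  # OOB disjoint from in-bag
        in_bag_size = round(0.632 * table.n_rows)
        assert counts.sum() == model.n_trees * in_bag_size
        assert counts.max() - counts.min() <= 1  # equal total appearances up to remainder

    def test_column_order_invariance(self):
        frame = _linear_frame(4, n=120)
        table = PredictorTable.from_frame(frame, "y")
        shuffled = PredictorTable.from_frame(
            frame[["z1", "y", "x1", "z0"]], "y"
        )
        m1 = lc.fit_forest(table, {"n_trees": 30}, seed=9)
        m2 = lc.fit_forest(shuffled, {"n_trees": 30}, seed=9)
        assert np.array_equal(predict(m1, table), predict(m2, shuffled))
        assert lc.oob_r2(m1, table) == lc.oob_r2(m2, shuffled)

    def test_categorical_level_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        n = 150
        g = rng.integers(0, 3, n)
        y = np.array([0.0, 1.0, 2.5])[g] + 0.3 * rng.normal(size=n)
        f1 = pd.DataFrame({"g": pd.Series(g).map({0: "aa", 1: "bb", 2: "cc"}),
                           "x": rng.normal(size=n), "y": y})
        f2 = f1.assign(g=f1["g"].map({"aa": "qq", "bb": "mm", "cc": "zz"}))
        t1 = PredictorTable.from_frame(f1, "y")
        t2 = PredictorTable.from_frame(f2, "y")
        m1 = lc.fit_forest(t1, {"n_trees": 30}, seed=3)
        m2 = lc.fit_forest(t2, {"n_trees": 30}, seed=3)
        assert np.allclose(predict(m1, t1), predict(m2, t2))

    def test_contract_errors(self):
        frame = _linear_frame(6, n=60)
        table = PredictorTable.from_frame(frame, "y")
        with pytest.raises(ValueError, match="mtry"):
            lc.fit_forest(table, {"mtry": 10}, seed=0)
        const = PredictorTable.from_frame(frame.assign(y=1.0), "y")
        with pytest.raises(ValueError, match="constant"):
            lc.fit_forest(const, {"n_trees": 5}, seed=0)
        tiny = PredictorTable.from_frame(frame.head(20), "y")
        with pytest.raises(ValueError, match="50"):
            lc.fit_forest(tiny, {"n_trees": 5}, seed=0)


class TestOobR2:
    def _stub_model(self, preds_tree, n):
        tree = _Tree(
            feature=np.array([0]), threshold=np.array([0.5]), cat_left=[None],
            left=np.array([-1]), right=np.array([-1]),
            value=np.array([np.nan]), split_points={},
        )
        # single-split stub: overwrite with a 3-node tree
        tree.feature = np.array([0, -1, -1])
        tree.threshold = np.array([0.5, np.nan, np.nan])
        tree.cat_left = [None, None, None]
        tree.left = np.array([1, -1, -1])
        tree.right = np.array([2, -1, -1])
        tree.value = np.array([np.nan, preds_tree[0], preds_tree[1]])
        return ForestModel(
            trees=[tree], in_bag=[np.array([], dtype=int)],
            oob=[np.arange(n)], params={}, seed=0,
            feature_names=["x"], is_categorical=np.array([False]), n_rows=n,
        )

    def test_perfect_oob_predictions_give_one(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([2.0, 2.0, 5.0, 5.0])
        table = PredictorTable(x[:, None], y, ["x"], np.array([False]), {})
        model = self._stub_model((2.0, 5.0), 4)
        assert lc.oob_r2(model, table) == pytest.approx(1.0)

    def test_mean_prediction_gives_zero(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([2.0, 2.0, 5.0, 5.0])
        table = PredictorTable(x[:, None], y, ["x"], np.array([False]), {})
        model = self._stub_model((3.5, 3.5), 4)
        assert lc.oob_r2(model, table) == pytest.approx(0.0)

    def test_generating_r2_recovered_from_cohort(self, codebook):
        cfg = lc.GeneratorConfig(
            n_participants=1000, n_noise_predictors=3, outcome_target_r2=0.6, seed=21
        )
        dataset, truth = lc.generate_population(cfg)
        scored = lc.attach_scores(dataset, codebook)
        may, nov = scored.wave("may"), scored.wave("november")
        frame = pd.DataFrame(
            {
                "prior_mood": may["mood_score"],
                "worries": may["worries_score"],
                "subtype": truth.labels["may"].astype(float),
                **{c: may[c] for c in may.columns if c.startswith("noise_")},
                "outcome": nov["mood_followup"],
            }
        )
        table = PredictorTable.from_frame(frame, "outcome", categorical=["subtype"])
        model = lc.fit_forest(table, {"n_trees": 150}, seed=22)
        assert lc.oob_r2(model, table) == pytest.approx(0.6, abs=0.10)


class TestImportance:
    def test_irrelevant_predictor_near_zero(self):
        vals = []
        for seed in range(10):
            frame = _linear_frame(seed, n=150, n_noise=1)
            table = PredictorTable.from_frame(frame, "y")
            model = lc.fit_forest(table, {"n_trees": 60}, seed=seed)
            imp = lc.conditional_importance(model, table, n_permutations=3, seed=seed)
            vals.append(
                imp.to_frame().set_index("feature").loc["z0", "conditional_importance"]
            )
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_planted_relevance_ranked_first(self):
        wins = 0
        for seed in range(10):
            frame = _linear_frame(seed, n=200, n_noise=1)
            table = PredictorTable.from_frame(frame, "y")
            model = lc.fit_forest(table, {"n_trees": 60}, seed=seed)
            imp = lc.conditional_importance(model, table, n_permutations=3, seed=seed)
            tab = imp.to_frame().set_index("feature")
            wins += (
                tab.loc["x1", "rank"] == 1
                and tab.loc["x1", "conditional_importance"]
                > tab.loc["z0", "conditional_importance"]
            )
        assert wins >= 9

    def test_decoy_conditional_below_marginal(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            x1 = rng.normal(0, 1, n)
            decoy = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.normal(0, 1, n)
            frame = pd.DataFrame(
                {"x1": x1, "decoy": decoy, "z": rng.normal(0, 1, n),
                 "y": x1 + 0.5 * rng.normal(0, 1, n)}
            )
            table = PredictorTable.from_frame(frame, "y")
            model = lc.fit_forest(table, {"n_trees": 80}, seed=seed)
            imp = lc.conditional_importance(model, table, n_permutations=3, seed=seed)
            tab = imp.to_frame().set_index("feature")
            wins += (
                tab.loc["decoy", "conditional_importance"]
                < tab.loc["decoy", "marginal_importance"]
            )
            assert "x1" in tab.loc["decoy", "conditioning_set"].split(";")
        assert wins >= 9

    def test_duplicated_predictor_importance_splits(self):
        """An exact copy column shares the original's importance.

        Each copy individually carries clearly less than the lone
        predictor's importance, while their sum stays comparable to it.
        Full permutation importance is mildly subadditive under
        duplication (the intact copy compensates at unaffected splits), so
        the sum is tested as a band around the original, not as equality.
        """
        singles, copies, sums = [], [], []
        for seed in range(10):
            frame = _linear_frame(seed, n=150, n_noise=0)
            t_single = PredictorTable.from_frame(frame, "y")
            t_dup = PredictorTable.from_frame(
                frame.assign(x1_copy=frame["x1"]), "y"
            )
            m1 = lc.fit_forest(t_single, {"n_trees": 60, "mtry": 1}, seed=seed)
            m2 = lc.fit_forest(t_dup, {"n_trees": 60, "mtry": 1}, seed=seed)
            i1 = lc.conditional_importance(m1, t_single, assoc_threshold=1.0,
                                           n_permutations=3, seed=seed)
            i2 = lc.conditional_importance(m2, t_dup, assoc_threshold=1.0,
                                           n_permutations=3, seed=seed)
            tab1 = i1.to_frame().set_index("feature")
            tab2 = i2.to_frame().set_index("feature")
            singles.append(tab1.loc["x1", "conditional_importance"])
            copies.append(max(tab2.loc["x1", "conditional_importance"],
                              tab2.loc["x1_copy", "conditional_importance"]))
            sums.append(
                tab2.loc["x1", "conditional_importance"]
                + tab2.loc["x1_copy", "conditional_importance"]
            )
        singles, copies, sums = map(np.array, (singles, copies, sums))
        assert np.mean(copies) < 0.7 * np.mean(singles)
        assert 0.6 * np.mean(singles) < np.mean(sums) < 1.1 * np.mean(singles)

    def test_importance_is_seed_deterministic(self):
        frame = _linear_frame(7, n=120)
        table = PredictorTable.from_frame(frame, "y")
        model = lc.fit_forest(table, {"n_trees": 30}, seed=4)
        a = lc.conditional_importance(model, table, n_permutations=2, seed=8)
        b = lc.conditional_importance(model, table, n_permutations=2, seed=8)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())


class TestAssociationMatrix:
    def test_mixed_type_associations(self):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        g = (x > 0).astype(float)  # strongly tied to x
        frame = pd.DataFrame(
            {"x": x, "g": pd.Series(g).map({0.0: "lo", 1.0: "hi"}),
             "w": rng.normal(size=n), "y": rng.normal(size=n)}
        )
        table = PredictorTable.from_frame(frame, "y")
        assoc = predictor_association_matrix(table)
        names = table.feature_names
        i_x, i_g, i_w = names.index("x"), names.index("g"), names.index("w")
        assert assoc[i_x, i_g] > 0.5        # binarised x is close to g
        assert assoc[i_x, i_w] < 0.2        # independent numerics
        assert np.allclose(assoc, assoc.T)


class TestModelVariants:
    def _cohort_frame(self, seed, n=300):
        rng = np.random.default_rng(seed)
        subtype = rng.integers(0, 3, n)
        items = rng.normal(subtype[:, None] * 0.5, 1.0, size=(n, 4))
        y = items[:, 0] * 0.6 + 0.4 * subtype + 0.5 * rng.normal(size=n)
        frame = pd.DataFrame(items, columns=[f"it{j}" for j in range(4)])
        frame["prior"] = rng.normal(size=n)
        frame["subtype"] = subtype.astype(float)
        frame["state"] = rng.choice(["NY", "CA"], n)
        frame["country"] = rng.choice(["US", "UK"], n, p=[0.7, 0.3])
        frame["cont_idx"] = rng.normal(size=n)
        frame["y"] = y
        return frame

    def test_variant_column_bookkeeping(self):
        frame = self._cohort_frame(0)
        variants = lc.build_model_variants(
            frame, outcome="y", base_predictors=["prior"], subtype_col="subtype",
            item_cols=[f"it{j}" for j in range(4)],
        )
        assert variants["B"].n_features == variants["A"].n_features + 4 - 1

    def test_variant_c_requires_us_rows(self):
        frame = self._cohort_frame(1)
        frame["country"] = "UK"
        with pytest.raises(ValueError, match="US"):
            lc.build_model_variants(
                frame, outcome="y", base_predictors=["prior"], subtype_col="subtype",
                item_cols=[f"it{j}" for j in range(4)],
                oxcgrt_cols=["cont_idx"], us_mask=frame["country"] == "US",
            )

    def test_items_beyond_subtype_raise_r2(self):
        r2a, r2b = [], []
        for seed in range(6):
            frame = self._cohort_frame(seed)
            variants = lc.build_model_variants(
                frame, outcome="y", base_predictors=["prior"], subtype_col="subtype",
                item_cols=[f"it{j}" for j in range(4)],
            )
            ma = lc.fit_forest(variants["A"], {"n_trees": 60}, seed=seed)
            mb = lc.fit_forest(variants["B"], {"n_trees": 60}, seed=seed)
            r2a.append(lc.oob_r2(ma, variants["A"]))
            r2b.append(lc.oob_r2(mb, variants["B"]))
        assert np.mean(r2b) >= np.mean(r2a)
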