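import itertools

import numpy as np
import pandas as pd
import pytest

from vagmet import prediction as pred
from vagmet.cohort_io import CohortMetadata, TaxaTable
from vagmet.prediction import (
    FAST_SPACE,
    StubLearner,
    apply_external,
    attribute_features,
    build_fold_plan,
    compare_auroc,
    clinical_features,
    evaluate,
    fit_composite,
    lightgbm_factory,
    microbiome_features,
    nested_cv,
    race_strata,
    sample_hyperparameters,
    select_final_model,
    stub_factory,
    tune_nested,
)

from conftest import toy_metadata


@pytest.fixture(scope="module")
def meta232(cohort_meta=None):
    from vagmet.simulate import SimulationConfig, generate_cohort

    _, _, metadata, *_ = generate_cohort(SimulationConfig(seed=8))
    return metadata


class TestFoldPlan:
    def test_partition_property(self, meta232):
        plan = build_fold_plan(meta232, 10, 3, stratify_race=True, seed=0)
        for repeat in range(3):
            ids = sorted(s for f in range(10) for s in plan.test_ids(repeat, f))
            assert ids == sorted(meta232.sample_ids)
            assert set(plan.train_ids(repeat, 0)).isdisjoint(plan.test_ids(repeat, 0))

    def test_case_balance_within_two(self, meta232):
        """GAB-decile stratification keeps the case/control split of every
        fold within +-2 samples of the proportional share."""
        plan = build_fold_plan(meta232, 10, 2, stratify_race=True, seed=1)
        y = meta232.outcome_binary()
        expected = y.sum() / 10
        for (repeat, fold), ids in plan.assignment.items():
            assert abs(y.loc[ids].sum() - expected) <= 2

    def test_deterministic(self, meta232):
        p1 = build_fold_plan(meta232, 10, 2, seed=5)
        p2 = build_fold_plan(meta232, 10, 2, seed=5)
        assert p1.assignment == p2.assignment

    def test_too_many_folds_rejected(self):
        meta = toy_metadata(["sPTB", "TB", "TB", "sPTB"])
        with pytest.raises(ValueError):
            build_fold_plan(meta, 10, 1)


class TestHyperparameters:
    def test_draws_within_declared_space(self):
        draws = sample_hyperparameters(FAST_SPACE, 200, seed=0)
        for hp in draws:
            assert hp["fs_method"] in FAST_SPACE["fs_method"]
            assert hp["pca"] in FAST_SPACE["pca"]
            lo, hi = FAST_SPACE["learner"]["learning_rate"][1:]
            assert lo <= hp["learner"]["learning_rate"] <= hi

    def test_reproducible(self):
        assert sample_hyperparameters(FAST_SPACE, 5, seed=3) == sample_hyperparameters(
            FAST_SPACE, 5, seed=3
        )

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            sample_hyperparameters({}, 1)


class TestTuneNested:
    def test_sixth_by_r2_never_selected(self):
        """A candidate outside the top five by R^2 cannot win, even with
        the globally best auROC."""
        r2 = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        auc = np.array([0.6, 0.6, 0.6, 0.6, 0.6, 0.99])
        assert tune_nested(r2, auc) != 5

    def test_best_auroc_among_top_five_wins(self):
        r2 = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        auc = np.array([0.6, 0.7, 0.65, 0.72, 0.6, 0.99])
        assert tune_nested(r2, auc) == 3

    def test_dominant_candidate_selected(self):
        assert tune_nested(np.array([0.2, 0.9]), np.array([0.5, 0.9])) == 1

    def test_single_candidate_returned(self):
        assert tune_nested(np.array([0.1]), np.array([0.5])) == 0

    def test_tie_broken_by_draw_order(self):
        assert tune_nested(np.array([0.5, 0.5]), np.array([0.7, 0.7])) == 0

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError):
            tune_nested(np.array([np.nan]), np.array([np.nan]))


def small_training_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 6)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(6)],
    )
    y_arr = (X["f0"] + 0.5 * rng.normal(size=n) > 0).astype(int)
    meta = toy_metadata(
        ["sPTB" if v else "TB" for v in y_arr],
        race=list(np.where(rng.random(n) < 0.6, "Black", "White")),
    )
    X.index = meta.sample_ids
    return X, meta.outcome_binary(), meta


class TestComposite:
    def test_stratum_isolation(self):
        """Predictions for one stratum are untouched when the other
        stratum's training data is perturbed."""
        X, y, meta = small_training_data()
        strata = race_strata(meta)
        hp = {"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}}
        m1 = fit_composite(X, y, strata, hp, stub_factory, seed=0)
        X2 = X.copy()
        X2.loc[strata == "non-Black"] += 100.0
        m2 = fit_composite(X2, y, strata, hp, stub_factory, seed=0)
        black = strata.index[strata == "Black"]
        s1 = m1.predict(X.loc[black], strata)
        s2 = m2.predict(X.loc[black], strata)
        assert np.allclose(s1, s2)

    def test_single_class_stratum_rejected(self):
        X, y, meta = small_training_data()
        strata = race_strata(meta)
        y2 = y.copy()
        y2.loc[strata == "non-Black"] = 0
        with pytest.raises(ValueError, match="non-Black"):
            fit_composite(X, y2, strata, {"learner": {}}, stub_factory, seed=0)

    def test_pooled_equals_per_stratum_concatenation(self):
        X, y, meta = small_training_data(seed=2)
        strata = race_strata(meta)
        hp = {"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}}
        model = fit_composite(X, y, strata, hp, stub_factory, seed=0)
        pooled = model.predict(X, strata)
        parts = []
        for key in model.strata:
            ids = [i for i in X.index if strata[i] == key]
            parts.append(model.predict(X.loc[ids], strata))
        concat = pd.concat(parts).loc[pooled.index]
        assert (pooled == concat).all()  # exact equality, not approximate

    def test_microbiome_load_imputed_from_training_mean(self):
        rel = np.array([[0.5, 0.5], [0.25, 0.75], [1.0, 0.0], [0.4, 0.6]])
        load = np.array([100.0, 300.0, np.nan, 500.0])
        taxa = TaxaTable([f"s{i}" for i in range(4)], ["t0", "t1"], rel, load)
        feats = microbiome_features(taxa, train_ids=["s0", "s1"])
        assert np.allclose(feats.loc["s2"], [200.0, 0.0])  # mean of training loads


class TestEvaluate:
    @staticmethod
    def scored_meta(scores, outcomes, gab=None):
        meta = toy_metadata(outcomes, gab=gab)
        return pd.Series(scores, index=meta.sample_ids), meta

    def test_perfect_separation(self):
        s, meta = self.scored_meta([0.9, 0.8, 0.1, 0.2], ["sPTB", "sPTB", "TB", "TB"])
        assert evaluate(s, meta).auroc == 1.0

    def test_all_tied_scores_give_half(self):
        s, meta = self.scored_meta([0.5] * 6, ["sPTB"] * 3 + ["TB"] * 3)
        assert evaluate(s, meta).auroc == 0.5

    def test_worked_example_matches_pair_counting(self):
        scores = [0.9, 0.8, 0.4, 0.2]
        labels = [1, 0, 1, 0]
        s, meta = self.scored_meta(scores, ["sPTB", "TB", "sPTB", "TB"])
        # brute-force concordant-pair oracle over the 4 case-control pairs
        pairs = [(i, j) for i in range(4) for j in range(4) if labels[i] == 1 and labels[j] == 0]
        conc = np.mean([
            1.0 if scores[i] > scores[j] else 0.5 if scores[i] == scores[j] else 0.0
            for i, j in pairs
        ])
        assert conc == 0.75
        assert evaluate(s, meta).auroc == pytest.approx(conc)

    def test_reclassification_reuses_scores_exactly(self):
        s, meta = self.scored_meta(
            [0.9, 0.7, 0.4, 0.2, 0.1],
            ["sPTB", "sPTB", "sPTB", "TB", "TB"],
            gab=[27.0, 31.0, 35.0, 39.0, 40.0],
        )
        r_sptb = evaluate(s, meta, "sPTB")
        r_32 = evaluate(s, meta, "GAB<32")
        assert r_sptb.scores == r_32.scores  # byte-identical score vectors
        assert r_32.labels != r_sptb.labels

    def test_single_class_rejected(self):
        s, meta = self.scored_meta([0.5, 0.6], ["TB", "TB"])
        with pytest.raises(ValueError):
            evaluate(s, meta)


class TestCompareAuroc:
    def test_identical_scores(self):
        y = pd.Series([1, 0, 1, 0], index=list("abcd"))
        s = pd.Series([0.9, 0.2, 0.7, 0.4], index=list("abcd"))
        z, p = compare_auroc(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_hanley_mcneil_closed_form(self):
        """At auROC = 0.5 with 50/50 labels the Hanley-McNeil variance is
        (A(1-A) + 49(Q1-A^2) + 49(Q2-A^2)) / 2500 with
        Q1 = A/(2-A) = 1/3 and Q2 = 2A^2/(1+A) = 1/3."""
        from vagmet.prediction import _hanley_mcneil_se

        expected = np.sqrt((0.25 + 49 * (1 / 3 - 0.25) + 49 * (1 / 3 - 0.25)) / 2500)
        assert _hanley_mcneil_se(0.5, 50, 50) == pytest.approx(expected)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(40)]
        y = pd.Series(rng.integers(0, 2, 40), index=idx)
        y.iloc[:5] = 1
        y.iloc[5:10] = 0
        a = pd.Series(rng.random(40), index=idx)
        b = pd.Series(rng.random(40), index=idx)
        z1, p1 = compare_auroc(a, b, y)
        z2, p2 = compare_auroc(b, a, y)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_labels_rejected(self):
        y = pd.Series([1, 1], index=list("ab"))
        s = pd.Series([0.5, 0.6], index=list("ab"))
        with pytest.raises(ValueError):
            compare_auroc(s, s, y)


class TestFinalModelAndExternal:
    def test_strict_maximum_selected(self):
        X, y, meta = small_training_data(seed=4)
        hps = [
            {"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}},
            {"fs_method": "rank_corr", "fs_keep": 0.5, "pca": None, "learner": {}},
        ]
        model, table = select_final_model(X, meta, hps, composite=False,
                                          learner_factory=stub_factory, seed=0)
        best_row = table.loc[table["training_fit_auroc"].idxmax()]
        assert model.hp == hps[int(best_row["candidate"])]
        assert (table["metric"] == "training_fit").all()

    def test_identical_candidates_first_returned(self):
        X, y, meta = small_training_data(seed=4)
        hp = {"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}}
        model, table = select_final_model(X, meta, [hp, hp], composite=False,
                                          learner_factory=stub_factory, seed=0)
        assert table["training_fit_auroc"].nunique() == 1

    def test_empty_candidates_rejected(self):
        X, y, meta = small_training_data()
        with pytest.raises(ValueError):
            select_final_model(X, meta, [], learner_factory=stub_factory)

    def test_external_identity_when_features_match(self):
        X, y, meta = small_training_data(seed=5)
        hp = {"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}}
        model = fit_composite(X, y, None, hp, stub_factory, seed=0)
        scores, overlap = apply_external(model, X)
        internal = model.predict(X, pd.Series("all", index=X.index))
        assert overlap == 1.0
        assert np.allclose(scores, internal)

    def test_partial_overlap_fraction_and_determinism(self):
        X, y, meta = small_training_data(seed=6)
        hp = {"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}}
        model = fit_composite(X, y, None, hp, stub_factory, seed=0)
        external = X[["f0", "f1"]]
        s1, overlap = apply_external(model, external)
        s2, _ = apply_external(model, external)
        assert overlap == pytest.approx(2 / 6)
        assert (s1 == s2).all()

    def test_zero_overlap_rejected(self):
        X, y, meta = small_training_data(seed=6)
        hp = {"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}}
        model = fit_composite(X, y, None, hp, stub_factory, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            apply_external(model, X.rename(columns=lambda c: "z" + c))


@pytest.fixture(scope="module")
def tree_model():
    rng = np.random.default_rng(7)
    n = 120
    X = pd.DataFrame(
        {"signal": rng.normal(size=n), "flat1": np.zeros(n), "flat2": np.zeros(n)},
        index=[f"s{i}" for i in range(n)],
    )
    y = pd.Series((X["signal"] > 0).astype(int).to_numpy(), index=X.index)
    hp = {"fs_method": "none", "fs_keep": 1.0, "pca": None,
          "learner": {"n_estimators": 20, "num_leaves": 7}}
    return X, fit_composite(X, y, None, hp, lightgbm_factory, seed=0)


class TestAttribution:

    def test_single_informative_feature_gets_all_mass(self, tree_model):
        X, model = tree_model
        fa = attribute_features(model, X.iloc[:20])
        mass = dict(fa.ranking)
        assert mass["signal"] > 0
        assert mass["flat1"] == 0 and mass["flat2"] == 0

    def test_additivity_to_raw_margin(self, tree_model):
        X, model = tree_model
        fa = attribute_features(model, X.iloc[:30])
        pipe = model.pipelines["all"]
        raw = model.learners["all"].booster_.predict(pipe.transform(X.iloc[:30]), raw_score=True)
        assert np.allclose(fa.contributions.sum(axis=1) + fa.baseline, raw, atol=1e-6)

    def test_ranking_stable_under_sample_reordering(self, tree_model):
        X, model = tree_model
        r1 = attribute_features(model, X.iloc[:40]).ranking
        r2 = attribute_features(model, X.iloc[:40].iloc[::-1]).ranking
        assert [f for f, _ in r1] == [f for f, _ in r2]

    def test_non_tree_learner_rejected(self):
        X = pd.DataFrame({"f0": np.arange(20.0)}, index=[f"s{i}" for i in range(20)])
        y = pd.Series(([0, 1] * 10), index=X.index)
        model = fit_composite(X, y, None, {"learner": {}}, stub_factory, seed=0)
        with pytest.raises(ValueError, match="tree"):
            attribute_features(model, X)


class TestNestedCVSmoke:
    def test_out_of_fold_scores_cover_cohort(self):
        X, y, meta = small_training_data(n=80, seed=9)
        cands = [{"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}}]
        report, selected = nested_cv(
            X, meta, cands, composite=False, stratify_race=False,
            n_outer_folds=4, n_outer_repeats=2, n_inner_folds=3, n_inner_repeats=1,
            learner_factory=stub_factory, seed=0,
        )
        assert sorted(report.scores) == sorted(meta.sample_ids)
        assert len(report.per_repeat_auroc) == 2
        assert len(selected) == 8

    def test_deterministic_given_seed(self):
        X, y, meta = small_training_data(n=60, seed=10)
        cands = [{"fs_method": "none", "fs_keep": 1.0, "pca": None, "learner": {}},
                 {"fs_method": "rank_corr", "fs_keep": 0.5, "pca": None, "learner": {}}]
        kw = dict(composite=False, stratify_race=False, n_outer_folds=3,
                  n_outer_repeats=1, n_inner_folds=3, n_inner_repeats=1,
                  learner_factory=stub_factory, seed=4)
        r1, _ = nested_cv(X, meta, cands, **kw)
        r2, _ = nested_cv(X, meta, cands, **kw)
        assert r1.scores == r2.scores
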