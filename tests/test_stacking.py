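import numpy as np
import pandas as pd
import pytest

import mvstack as mv
from mvstack.learners import encode_clinical
from mvstack.stacking import StackingError, stratified_fold_assignment

from conftest import make_two_view


def dummy_spec(name="DUMMY", view=mv.MICROBIAL_VIEW, seed=0):
    return mv.BaseLearnerSpec(name=name, family="dummy-prior", view=view, seed=seed)


class TestDefaultSuite:
    def test_both_views_give_eight_named_learners(self):
        specs = mv.default_suite([mv.MICROBIAL_VIEW, mv.CLINICAL_VIEW])
        assert [s.name for s in specs] == [
            "SGD_LL", "SGD_HL", "KNN", "MLP", "QDA", "RF", "HGBC_otu", "HGBC_clin",
        ]
        assert all(s.view == mv.MICROBIAL_VIEW for s in specs[:7])
        assert specs[-1].view == mv.CLINICAL_VIEW
        assert specs[-1].supports_missing and specs[-1].supports_categorical

    def test_microbial_only_gives_seven(self):
        assert len(mv.default_suite([mv.MICROBIAL_VIEW])) == 7

    def test_clinical_only_rejected(self):
        with pytest.raises(ValueError, match="microbial"):
            mv.default_suite([mv.CLINICAL_VIEW])

    def test_unknown_view_rejected(self):
        with pytest.raises(ValueError, match="unknown view"):
            mv.default_suite([mv.MICROBIAL_VIEW, "proteomic"])

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            mv.BaseLearnerSpec(name="X", family="svm", view=mv.MICROBIAL_VIEW)


class TestEncodeClinical:
    def test_unseen_level_maps_to_missing(self):
        train = pd.DataFrame({"sex": pd.Categorical(["F", "M", "F"])})
        X, mask, cats = encode_clinical(train)
        assert mask.tolist() == [True]
        test = pd.DataFrame({"sex": pd.Categorical(["X", "M", None])})
        Xt, _, _ = encode_clinical(test, cats)
        assert np.isnan(Xt[0, 0]) and np.isnan(Xt[2, 0])
        assert Xt[1, 0] == cats["sex"].index("M")


class TestBuildMetaFeatures:
    def test_shape_and_range(self):
        ds = make_two_view(n=20, seed=1)
        specs = [dummy_spec(f"D{i}") for i in range(3)]
        meta = mv.build_meta_features(ds, specs, k=5, seed=0)
        assert meta.values.shape == (20, 3)
        assert meta.column_names == ["D0", "D1", "D2"]
        assert set(meta.fold_of_sample) == {1, 2, 3, 4, 5}
        arr = meta.values.to_numpy()
        assert ((arr >= 0) & (arr <= 1)).all()

    def test_prevalence_learner_reproduces_fold_complement_prevalence(self):
        """A prior-predicting learner's column is the training-fold prevalence."""
        ds = make_two_view(n=24, n_pos=8, seed=2)
        meta = mv.build_meta_features(ds, [dummy_spec()], k=4, seed=3)
        y = ds.labels.to_numpy()
        folds = meta.fold_of_sample.to_numpy()
        for f in np.unique(folds):
            expected = y[folds != f].mean()
            got = meta.values.to_numpy()[folds == f, 0]
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_deterministic_given_seed(self):
        ds = make_two_view(n=30, n_pos=10, seed=4)
        specs = mv.default_suite([mv.MICROBIAL_VIEW, mv.CLINICAL_VIEW], seed=0)[:3]
        a = mv.build_meta_features(ds, specs, k=3, seed=9)
        b = mv.build_meta_features(ds, specs, k=3, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_k_exceeding_minority_count_rejected(self):
        ds = make_two_view(n=12, n_pos=3, seed=5)
        with pytest.raises(StackingError, match="minority"):
            mv.build_meta_features(ds, [dummy_spec()], k=4, seed=0)

    def test_matches_handrolled_two_fold_oracle(self):
        """k=2 out-of-fold construction equals an explicit two-fold loop."""
        ds = make_two_view(n=10, n_pos=4, seed=6)
        spec = mv.BaseLearnerSpec(
            name="SGD_LL", family="sgd-logistic", view=mv.MICROBIAL_VIEW,
            use_class_weights=True, seed=0,
        )
        y = ds.labels.to_numpy()
        folds = stratified_fold_assignment(y, 2, seed=1)
        filt = mv.fit_view_filter(ds.views[mv.MICROBIAL_VIEW], y, alpha=1.0, correction="none")
        meta = mv.build_meta_features(
            ds, [spec], k=2, seed=1, filter_state=filt, folds=folds
        )

        # independent two-fold loop over the same preprocessed matrix
        from mvstack.stacking import _fit_one
        X = filt.transform(ds.views[mv.MICROBIAL_VIEW]).to_numpy()
        cw = mv.compute_class_weights(y)
        expected = np.empty(10)
        for f in (1, 2):
            model = _fit_one(spec, X[folds != f], y[folds != f], cw, None, ("fold", int(f)))
            from mvstack.learners import positive_proba
            expected[folds == f] = positive_proba(model, X[folds == f])
        np.testing.assert_array_equal(meta.values.to_numpy()[:, 0], expected)


class TestMetaLearner:
    def test_perfect_predictor_column_dominates(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 20)
        M = np.column_stack([rng.random(40), y.astype(float), rng.random(40)])
        fit = mv.fit_meta_learner(M, y, k=4, seed=0)
        assert fit.cv_score == pytest.approx(1.0)
        assert np.argmax(np.abs(fit.coef_)) == 1

    def test_constant_matrix_predicts_prevalence(self):
        y = np.array([1] * 3 + [0] * 9)
        M = np.full((12, 2), 0.5)
        fit = mv.fit_meta_learner(M, y, k=3, seed=0)
        proba = fit.model.predict_proba(M)[:, list(fit.model.classes_).index(1)]
        np.testing.assert_allclose(proba, y.mean(), atol=0.15)

    def test_single_grid_point_is_selected(self):
        y = np.array([0, 1] * 10)
        M = np.random.default_rng(1).random((20, 2))
        fit = mv.fit_meta_learner(M, y, Cs=[0.5], l1_ratios=[0.25], k=2, seed=0)
        assert fit.chosen_params == {"C": 0.5, "l1_ratio": 0.25}

    def test_degenerate_labels_rejected(self):
        with pytest.raises(StackingError, match="degenerate"):
            mv.fit_meta_learner(np.random.rand(6, 2), np.zeros(6, dtype=int))

    def test_random_forest_meta_has_no_weights(self):
        y = np.array([0, 1] * 10)
        M = np.random.default_rng(2).random((20, 2))
        fit = mv.fit_meta_learner(M, y, kind="random-forest", seed=0)
        assert not fit.is_linear
        with pytest.raises(AttributeError):
            fit.coef_


class TestSoftVote:
    @pytest.mark.parametrize(
        "row, score, label",
        [((0.9, 0.8, 0.4), 0.7, 1), ((0.5, 0.5), 0.5, 0), ((0.2, 0.3), 0.25, 0)],
    )
    def test_arithmetic_and_tie_rule(self, row, score, label):
        labels, scores = mv.soft_vote(np.array([row]))
        assert scores[0] == pytest.approx(score)
        assert labels[0] == label

    def test_single_column_thresholds_base_learner(self):
        P = np.array([[0.9], [0.4], [0.51]])
        labels, scores = mv.soft_vote(P)
        np.testing.assert_array_equal(labels, [1, 0, 1])
        np.testing.assert_array_equal(scores, P[:, 0])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            mv.soft_vote(np.empty((0, 2)))
        with pytest.raises(ValueError):
            mv.soft_vote(np.empty((3, 0)))

    def test_agrees_with_equal_weight_meta_labels(self):
        """Equal meta weights + matched intercept reproduce soft-vote labels."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        P = rng.random((50, 4))
        lr = LogisticRegression()
        lr.fit(P, (P.mean(axis=1) > 0.5).astype(int))  # just to shape the model
        beta = 3.0
        lr.coef_ = np.full((1, 4), beta)
        lr.intercept_ = np.array([-beta * 4 * 0.5])
        meta_labels = lr.predict(P)
        vote_labels, _ = mv.soft_vote(P)
        np.testing.assert_array_equal(meta_labels, vote_labels)


class TestStackedModel:
    def test_fit_produces_eight_learners_and_weights(self, fitted_small):
        _, results = fitted_small
        assert len(results.fitted_bases) == 8
        assert len(results.meta.coef_) == 8
        assert results.meta.chosen_params.keys() == {"C", "l1_ratio"}

    def test_predictions_are_probabilities(self, fitted_small):
        split, results = fitted_small
        p = results.predict_proba(split.train)
        assert p.shape == (split.train.n_samples,)
        assert np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()
        one = split.test.subset(split.test.sample_ids[:1])
        assert results.predict_proba(one).shape == (1,)

    def test_zeroed_meta_outputs_half(self, fitted_small):
        split, results = fitted_small
        model = results.meta.model
        saved = (model.coef_.copy(), model.intercept_.copy())
        try:
            model.coef_[:] = 0.0
            model.intercept_[:] = 0.0
            np.testing.assert_allclose(results.predict_proba(split.test), 0.5)
        finally:
            model.coef_, model.intercept_ = saved

    def test_microbial_only_path_has_seven_columns(self):
        ds = make_two_view(n=40, n_pos=14, seed=7)
        micro_only = mv.MultiViewDataset(
            views={mv.MICROBIAL_VIEW: ds.views[mv.MICROBIAL_VIEW]},
            labels=ds.labels,
            feature_meta={
                k: m for k, m in ds.feature_meta.items() if m.view == mv.MICROBIAL_VIEW
            },
        )
        cfg = mv.StackingConfig(seed=0, k=3, alpha=1.0, correction="none")
        res = mv.fit_stacked(micro_only, cfg)
        assert res.meta_features.values.shape[1] == 7

    def test_random_forest_meta_variant(self):
        ds = make_two_view(n=40, n_pos=14, seed=8)
        cfg = mv.StackingConfig(
            seed=0, k=3, alpha=1.0, correction="none", meta_learner="random-forest"
        )
        res = mv.fit_stacked(ds, cfg)
        p = res.predict_proba(ds)
        assert ((p >= 0) & (p <= 1)).all()

    def test_soft_vote_from_results(self, fitted_small):
        split, results = fitted_small
        labels, scores = results.soft_vote(split.test)
        base = results.base_probabilities(split.test)
        np.testing.assert_allclose(scores, base.to_numpy().mean(axis=1))
        np.testing.assert_array_equal(labels, (scores > 0.5).astype(int))

    def test_summary_mentions_chosen_hyperparameters(self, fitted_small):
        _, results = fitted_small
        text = results.summary()
        assert "base learner" in text and "l1_ratio" in text


class TestNoLeakage:
    def test_own_label_mutation_leaves_row_unchanged(self):
        """Row i of the meta-feature matrix never depends on label i."""
        ds = make_two_view(n=40, n_pos=16, seed=10)
        y = ds.labels.to_numpy()
        folds = stratified_fold_assignment(y, 4, seed=2)
        filt = mv.fit_view_filter(ds.views[mv.MICROBIAL_VIEW], y, alpha=1.0, correction="none")
        specs = mv.default_suite([mv.MICROBIAL_VIEW, mv.CLINICAL_VIEW], seed=0)
        cw = mv.compute_class_weights(y)
        base = mv.build_meta_features(
            ds, specs, k=4, seed=2, filter_state=filt, class_weights=cw, folds=folds
        )
        for i in (0, 7):
            flipped = ds.labels.copy()
            flipped.iloc[i] = 1 - flipped.iloc[i]
            mutated = mv.MultiViewDataset(
                views=ds.views, labels=flipped, feature_meta=ds.feature_meta
            )
            other = mv.build_meta_features(
                mutated, specs, k=4, seed=2, filter_state=filt, class_weights=cw, folds=folds
            )
            np.testing.assert_array_equal(
                base.values.to_numpy()[i], other.values.to_numpy()[i]
            )
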