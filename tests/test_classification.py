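"""Class weighting, CV plans, ELM, metrics, and the model suite."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, precision_score, recall_score

from enofuse.classification import (
    ELMClassifier,
    class_weights,
    compute_metrics,
    make_cv_plan,
    predict_elm,
    run_suite,
    train_elm,
)


class TestClassWeights:
    def test_imbalanced_example(self):
        labels = ["ripe"] * 25 + ["unripe"] * 75
        w = class_weights(labels)
        assert w["ripe"] == pytest.approx(2.0)
        assert w["unripe"] == pytest.approx(100 / 150)

    def test_balanced_gives_unit_weights(self):
        w = class_weights(["a"] * 10 + ["b"] * 10)
        assert w == {"a": 1.0, "b": 1.0}

    def test_sample_weighted_mean_is_one(self, rng):
        labels = rng.choice(["a", "b", "c"], size=200, p=[0.6, 0.3, 0.1])
        w = class_weights(labels)
        mean_w = np.mean([w[label] for label in labels])
        assert mean_w == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_weights([])


class TestCVPlans:
    def _meta(self, n=100, n_days=25, seed=0):
        rng = np.random.default_rng(seed)
        ts = np.sort(rng.uniform(0, n_days * 24, n))
        return pd.DataFrame(
            {
                "label": ["ripe", "unripe"] * (n // 2),
                "day": (ts // 24).astype(int),
                "timestamp": ts,
            }
        )

    def test_leave_5_day_out_contiguous_blocks(self):
        meta = pd.DataFrame(
            {"label": ["a", "b"] * 50, "day": np.repeat(np.arange(25), 4)}
        )
        plan = make_cv_plan(meta, "leave_k_day_out", {"k": 5}, seed=0)
        assert plan.n_folds == 5
        days = meta["day"].to_numpy()
        seen_blocks = []
        for tr, te in plan.folds:
            te_days = np.unique(days[te])
            assert len(te_days) == 5
            assert np.all(np.diff(sorted(te_days)) == 1), "blocks are contiguous"
            assert not set(te_days) & set(np.unique(days[tr]))
            seen_blocks.append(tuple(te_days))
        assert len(set(seen_blocks)) == 5

    def test_stratified_10_fold_balance(self):
        meta = self._meta(100)
        plan = make_cv_plan(meta, "stratified_kfold", {"k": 10}, seed=1)
        labels = meta["label"].to_numpy()
        for _, te in plan.folds:
            vals, counts = np.unique(labels[te], return_counts=True)
            assert list(counts) == [5, 5]

    def test_group_24h_never_splits_a_day(self):
        meta = self._meta(120, n_days=30)
        plan = make_cv_plan(meta, "group_24h", {"k": 5}, seed=2)
        groups = (meta["timestamp"].to_numpy() // 24).astype(int)
        for tr, te in plan.folds:
            assert not set(groups[tr]) & set(groups[te])

    def test_too_few_days_rejected(self):
        meta = pd.DataFrame({"label": ["a", "b"], "day": [0, 1]})
        with pytest.raises(ValueError, match="days"):
            make_cv_plan(meta, "leave_k_day_out", {"k": 5}, seed=0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            make_cv_plan(self._meta(), "leave_one_out", seed=0)


def _blobs(n=100, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n // 2, 5)), rng.normal(gap, 1, (n // 2, 5))]
    )
    y = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    return X, y


class TestELM:
    def test_separable_blobs_high_train_accuracy(self):
        X, y = _blobs(200, gap=4.0)
        model = train_elm(X, y, hidden_units=200, ridge=1e-6, seed=1)
        preds = predict_elm(model, X)
        acc = np.mean([p.label == t for p, t in zip(preds, y)])
        assert acc >= 0.99

    def test_same_seed_identical_predictions(self):
        X, y = _blobs(80, gap=2.0, seed=3)
        p1 = train_elm(X, y, seed=5).predict(X)
        p2 = train_elm(X, y, seed=5).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_infinite_ridge_collapses_confidence(self):
        X, y = _blobs(60, gap=2.0)
        model = train_elm(X, y, hidden_units=50, ridge=1e12, seed=0)
        assert np.abs(model.beta_).max() < 1e-6
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba, 0.5, atol=1e-6)

    def test_matches_least_squares_oracle(self):
        """Output weights must solve the ridge normal equations exactly.

        Oracle: lstsq on the augmented system [H; sqrt(ridge) I] b = [t; 0],
        an independent route to the same minimiser.
        """
        for seed in range(3):
            X, y = _blobs(50, gap=1.0, seed=seed)
            ridge = 1e-3
            model = ELMClassifier(hidden_units=30, ridge=ridge, seed=seed).fit(X, y)
            H = model._hidden(X)
            t = np.where(y == model.classes_[1], 1.0, -1.0)
            A = np.vstack([H, np.sqrt(ridge) * np.eye(30)])
            b = np.concatenate([t, np.zeros(30)])
            beta_oracle = np.linalg.lstsq(A, b, rcond=None)[0]
            np.testing.assert_allclose(model.beta_, beta_oracle, atol=1e-8)
            np.testing.assert_allclose(
                model.decision_function(X), H @ beta_oracle, atol=1e-8
            )

    def test_rejects_bad_hyperparameters(self):
        with pytest.raises(ValueError):
            ELMClassifier(hidden_units=0)


class TestMetrics:
    def test_simple_accuracy(self):
        rep = compute_metrics(["a"] * 9 + ["b"], ["a"] * 10)
        assert rep.accuracy == pytest.approx(0.9)

    def test_single_class_predictions(self):
        rep = compute_metrics(["a"] * 10, ["a"] * 6 + ["b"] * 4)
        assert rep.recall["a"] == pytest.approx(1.0)
        assert rep.recall["b"] == pytest.approx(0.0)
        assert "precision[b]" in rep.zero_division_flags

    def test_confusion_worked_example(self):
        y_true = ["c1"] * 48 + ["c2"] * 52
        y_pred = ["c1"] * 40 + ["c2"] * 8 + ["c1"] * 2 + ["c2"] * 50
        rep = compute_metrics(y_pred, y_true)
        np.testing.assert_array_equal(rep.confusion, [[40, 8], [2, 50]])
        assert rep.accuracy == pytest.approx(0.90)
        assert rep.precision["c1"] == pytest.approx(40 / 42)

    def test_confusion_row_sums_are_class_counts(self, rng):
        y_true = rng.choice(["a", "b"], 50)
        y_pred = rng.choice(["a", "b"], 50)
        rep = compute_metrics(list(y_pred), list(y_true))
        for i, c in enumerate(rep.classes):
            assert rep.confusion[i].sum() == np.sum(y_true == c)

    def test_cross_check_against_sklearn(self, rng):
        y_true = rng.choice(["a", "b"], 200, p=[0.3, 0.7])
        y_pred = rng.choice(["a", "b"], 200)
        rep = compute_metrics(list(y_pred), list(y_true))
        assert rep.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert rep.precision["a"] == pytest.approx(
            precision_score(y_true, y_pred, pos_label="a")
        )
        assert rep.recall["b"] == pytest.approx(
            recall_score(y_true, y_pred, pos_label="b")
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics(["a"], ["a", "b"])


class TestSuite:
    @pytest.mark.parametrize("model", ["LR", "RF", "GB", "SVM", "MLP", "ELM"])
    def test_separable_data_all_models(self, model):
        X, y = _blobs(80, gap=5.0, seed=7)
        meta = pd.DataFrame({"label": y})
        plan = make_cv_plan(meta, "stratified_kfold", {"k": 5}, seed=7)
        rep = run_suite(X, y, plan, [model], n_repeats=1, base_seed=7)[model]
        assert rep.mean_accuracy >= 0.95

    def test_fixed_seeds_reproduce_bit_identically(self):
        X, y = _blobs(60, gap=1.5, seed=9)
        meta = pd.DataFrame({"label": y})
        plan = make_cv_plan(meta, "stratified_kfold", {"k": 5}, seed=9)
        r1 = run_suite(X, y, plan, ["LR", "ELM"], n_repeats=1, base_seed=9)
        r2 = run_suite(X, y, plan, ["LR", "ELM"], n_repeats=1, base_seed=9)
        for name in r1:
            np.testing.assert_array_equal(
                r1[name].fold_accuracies, r2[name].fold_accuracies
            )
            pd.testing.assert_frame_equal(r1[name].predictions, r2[name].predictions)

    def test_unknown_model_rejected(self):
        X, y = _blobs(20)
        meta = pd.DataFrame({"label": y})
        plan = make_cv_plan(meta, "stratified_kfold", {"k": 2}, seed=0)
        with pytest.raises(ValueError, match="unknown model"):
            run_suite(X, y, plan, ["CNN"], n_repeats=1)

    def test_retains_per_sample_predictions_with_confidence(self):
        X, y = _blobs(40, gap=2.0)
        meta = pd.DataFrame({"label": y})
        plan = make_cv_plan(meta, "stratified_kfold", {"k": 4}, seed=1)
        rep = run_suite(X, y, plan, ["SVM"], n_repeats=2, base_seed=1)["SVM"]
        df = rep.predictions
        assert set(df.columns) >= {"sample_id", "fold", "repeat", "label_pred",
                                   "confidence"}
        assert df["confidence"].between(0, 1).all()
        # each sample predicted exactly once per repeat
        assert df.groupby("repeat")["sample_id"].nunique().eq(40).all()
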