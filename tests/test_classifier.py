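"""Training, metrics, cross-validation, and importance introspection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfscore.classifier import (METRIC_NAMES, LabeledSet, compute_metrics,
                                cross_validate, feature_importance,
                                labeled_set_from_features, load_model, predict,
                                rank_auc, save_model, train)
from nfscore.spectral import FEATURE_NAMES, featurize_sequences
from nfscore.synthetic import (SyntheticSpec, gen_toy_pentamer_table,
                               gen_training_set)


def brute_force_auc(scores, labels):
    """Oracle: enumerate every positive/negative pair; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_sensitivity_specificity_arithmetic(self):
        m = compute_metrics(tp=85, fp=21, tn=79, fn=15)
        assert m["sensitivity"] == pytest.approx(0.85)
        assert m["specificity"] == pytest.approx(0.79)
        assert m["accuracy"] == pytest.approx(164 / 200)

    def test_perfect_classifier(self):
        m = compute_metrics(tp=50, fp=0, tn=50, fn=0)
        assert m["mcc"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(1.0)
        assert m["accuracy"] == pytest.approx(1.0)

    def test_mcc_zero_denominator_substitution(self):
        assert compute_metrics(tp=10, fp=0, tn=0, fn=0)["mcc"] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_metrics(tp=-1, fp=0, tn=1, fn=0)

    def test_separated_scores_auc_one(self):
        scores = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        m = compute_metrics(tp=5, fp=0, tn=5, fn=0, scores=scores, labels=labels)
        assert m["auc"] == pytest.approx(1.0)

    @given(seed=st.integers(min_value=0, max_value=5000))
    @settings(max_examples=30, deadline=None)
    def test_rank_auc_equals_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        # coarse grid forces score ties so the tie rule is exercised
        scores = rng.integers(0, 6, size=n) / 5.0
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert rank_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)


def toy_labeled_set(rng, n=60, separation=4.0):
    """Gaussian blobs in the HelT block only; other channels pure noise."""
    x = rng.normal(size=(n, 288))
    labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    helt = [FEATURE_NAMES.index(f"HelT_{k}") for k in range(1, 7)]
    x[np.ix_(labels == 1, helt)] += separation
    feats = pd.DataFrame(x, columns=FEATURE_NAMES)
    return labeled_set_from_features(feats, labels)


class TestTrainPredict:
    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(size=(10, 288)), columns=FEATURE_NAMES)
        data = labeled_set_from_features(feats, np.ones(10, int))
        with pytest.raises(ValueError, match="single-class"):
            train(data, n_trees=5, seed=0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        data = toy_labeled_set(rng)
        probe = pd.DataFrame(rng.normal(size=(20, 288)), columns=FEATURE_NAMES)
        p1 = train(data, n_trees=50, seed=9).vote_fractions(probe)
        p2 = train(data, n_trees=50, seed=9).vote_fractions(probe)
        assert np.array_equal(p1, p2)

    def test_metadata_records_defaults(self, model_small):
        meta = model_small.metadata
        assert meta["max_features_per_split"] == 16  # floor(sqrt(288))
        assert meta["n_trees"] == 200

    def test_predict_threshold_and_tie(self):
        rng = np.random.default_rng(2)
        data = toy_labeled_set(rng, n=40)
        model = train(data, n_trees=4, seed=0)  # few trees: ties possible
        fv = data.features.iloc[0]
        out = predict(model, fv)
        assert out["label"] == int(out["prob"] >= 0.5)
        assert 0.0 <= out["prob"] <= 1.0

    def test_feature_name_mismatch_rejected(self, model_small):
        bad = pd.Series(np.zeros(288), index=[f"X_{i}" for i in range(288)])
        with pytest.raises(ValueError, match="feature names"):
            predict(model_small, bad)

    def test_holdout_accuracy_on_separable_set(self, training_small, model_small):
        """Margin-generated data should be almost perfectly classifiable."""
        ts, data = training_small
        spec = SyntheticSpec(n_pos=100, n_neg=100, seed=77)
        table = gen_toy_pentamer_table("at_content")
        held = gen_training_set(spec)
        feats = featurize_sequences(held.sequences, table, ids=held.ids)
        probs = model_small.vote_fractions(feats)
        acc = np.mean((probs >= 0.5).astype(int) == held.labels)
        assert acc > 0.95

    def test_model_roundtrip(self, tmp_path, model_small, training_small):
        path = tmp_path / "model.joblib"
        save_model(model_small, path)
        loaded = load_model(path)
        _, data = training_small
        probe = data.features.iloc[:10]
        assert np.array_equal(loaded.vote_fractions(probe),
                              model_small.vote_fractions(probe))


class TestCrossValidate:
    def test_report_schema(self, training_small):
        _, data = training_small
        report = cross_validate(data, k=5, seed=3, n_trees=60)
        frame = report.to_frame()
        assert list(frame.index) == list(METRIC_NAMES)
        assert set(frame.columns) == {"mean", "sd"}
        assert set(report.confusion) == {"tp", "fp", "tn", "fn"}
        for m in METRIC_NAMES:
            assert 0.0 <= report.mean[m] <= 1.0

    def test_pooled_accuracy_is_weighted_fold_mean(self, training_small):
        _, data = training_small
        report = cross_validate(data, k=5, seed=3, n_trees=60)
        c = report.confusion
        pooled = (c["tp"] + c["tn"]) / sum(c.values())
        weighted = np.average(report.per_fold["accuracy"],
                              weights=report.per_fold["n"])
        assert pooled == pytest.approx(weighted)

    def test_class_too_small_for_folds(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(rng.normal(size=(12, 288)), columns=FEATURE_NAMES)
        labels = np.r_[np.ones(3, int), np.zeros(9, int)]
        data = labeled_set_from_features(feats, labels)
        with pytest.raises(ValueError, match="fewer than k"):
            cross_validate(data, k=5, seed=0, n_trees=10)

    def test_label_noise_does_not_help(self, training_small):
        """Flipping labels at increasing rates cannot raise CV accuracy."""
        _, data = training_small
        rng = np.random.default_rng(8)
        accs = []
        for eps in (0.0, 0.1, 0.3):
            labels = data.labels.copy()
            flip = rng.random(len(labels)) < eps
            labels[flip] = 1 - labels[flip]
            noisy = LabeledSet(data.features, labels, data.ids)
            accs.append(cross_validate(noisy, k=5, seed=5, n_trees=60).mean["accuracy"])
        assert accs[0] >= accs[1] - 0.03 >= accs[2] - 0.06


class TestFeatureImportance:
    def test_table_shape_and_nonnegativity(self, model_small):
        imp = feature_importance(model_small)
        assert len(imp) == 288
        assert (imp["importance"] >= 0).all()
        assert imp["importance"].is_monotonic_decreasing

    def test_helt_only_signal_tops_ranking(self):
        rng = np.random.default_rng(12)
        data = toy_labeled_set(rng, n=120, separation=3.0)
        model = train(data, n_trees=150, seed=1)
        imp = feature_importance(model)
        assert all(f.startswith("HelT_") for f in imp["feature"].head(5))

    def test_unfitted_model_rejected(self, model_small):
        from sklearn.ensemble import RandomForestClassifier

        from nfscore.classifier import NFModel
        bare = NFModel(RandomForestClassifier(), FEATURE_NAMES)
        with pytest.raises(ValueError, match="not fitted"):
            feature_importance(bare)
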