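"""Grouped splitting, oversampling, training protocol and metrics."""

import numpy as np
import pandas as pd
import pytest

from borylsite import (
    ModelConfig,
    compute_metrics,
    grouped_split,
    oversample_minority,
    predict_sites,
    run_protocol,
    train_classifier,
)
from borylsite.classify import FittedModel, child_seed
from borylsite.errors import ConfigError, SchemaError


class TestGroupedSplit:
    def test_eighty_twenty_arithmetic(self):
        groups = [f"S{i}" for i in range(10)]
        split = grouped_split(groups, fraction=0.8, seed=0)
        assert len(split.train_substrates) == 8
        assert len(split.test_substrates) == 2

    def test_disjoint_and_exhaustive(self):
        groups = [f"S{i}" for i in range(23)]
        split = grouped_split(groups, seed=5)
        assert not split.train_substrates & split.test_substrates
        assert split.train_substrates | split.test_substrates == set(groups)

    def test_determinism(self):
        groups = [f"S{i}" for i in range(15)]
        assert grouped_split(groups, seed=3) == grouped_split(groups, seed=3)

    def test_bad_fraction_raises(self):
        with pytest.raises(ConfigError):
            grouped_split(["a", "b"], fraction=1.5, seed=0)

    def test_rows_follow_their_substrate(self, small_table):
        split = grouped_split(small_table["substrate_id"], seed=1)
        in_train = small_table["substrate_id"].isin(split.train_substrates)
        train_subs = set(small_table.loc[in_train, "substrate_id"])
        test_subs = set(small_table.loc[~in_train, "substrate_id"])
        assert not train_subs & test_subs


class TestOversampling:
    def test_equalizes_189_798(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.normal(size=987)})
        y = pd.Series([1] * 189 + [0] * 798)
        X2, y2, _ = oversample_minority(X, y, seed=0)
        assert (y2 == 1).sum() == 798
        assert (y2 == 0).sum() == 798

    def test_balanced_input_unchanged(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        y = pd.Series([0, 0, 1, 1])
        X2, y2, _ = oversample_minority(X, y, seed=0)
        pd.testing.assert_frame_equal(X2, X)

    def test_added_rows_duplicate_minority_and_majority_untouched(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": rng.normal(size=50), "g": rng.normal(size=50)})
        y = pd.Series([1] * 10 + [0] * 40)
        X2, y2, _ = oversample_minority(X, y, seed=2)
        # original block preserved verbatim
        pd.testing.assert_frame_equal(X2.iloc[:50], X)
        minority_rows = {tuple(r) for r in X[y == 1].to_numpy()}
        for row in X2.iloc[50:].to_numpy():
            assert tuple(row) in minority_rows
        assert set(np.unique(X2[y2 == 1].to_numpy())) >= set(np.unique(X[y == 1].to_numpy()))

    def test_single_class_raises(self):
        with pytest.raises(ConfigError):
            oversample_minority(pd.DataFrame({"f": [1.0]}), pd.Series([1]), seed=0)


class _StubEstimator:
    """Fixed-probability estimator for threshold-convention checks."""

    def __init__(self, proba):
        self.proba = np.asarray(proba)

    def predict_proba(self, X):
        return np.column_stack([1 - self.proba, self.proba])


class TestPredictSites:
    def test_threshold_is_strict(self):
        model = FittedModel(_StubEstimator([0.34, 0.5, 0.51, 1.0]),
                            columns=["a"], normalize_rows=False)
        X = pd.DataFrame({"a": [0.0, 0.0, 0.0, 0.0]})
        out = predict_sites(model, X)
        # 0.34 < 0.5 -> no borylation; exactly 0.5 is also a negative call
        assert list(out["call"]) == [0, 0, 1, 1]

    def test_column_mismatch_raises(self):
        model = FittedModel(_StubEstimator([0.9]), columns=["a"], normalize_rows=False)
        with pytest.raises(SchemaError, match="missing columns"):
            predict_sites(model, pd.DataFrame({"b": [1.0]}))


class TestTrainClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": np.r_[rng.normal(-3, 0.1, 50), rng.normal(3, 0.1, 50)]})
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        model = train_classifier(X, y, ModelConfig(n_estimators=50), seed=0)
        out = predict_sites(model, X)
        assert (out["call"].to_numpy() == y).all()

    def test_determinism_same_seed(self, small_table):
        feats = [c for c in small_table.columns if c.endswith("_q_h")]
        X = small_table[feats]
        y = small_table["label"].to_numpy()
        m1 = train_classifier(X, y, ModelConfig(n_estimators=50), seed=9)
        m2 = train_classifier(X, y, ModelConfig(n_estimators=50), seed=9)
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_unknown_algorithm_raises(self):
        with pytest.raises(ConfigError, match="unknown algorithm"):
            train_classifier(pd.DataFrame({"a": [0.0, 1.0]}), [0, 1],
                             ModelConfig(algorithm="gnn"), seed=0)

    def test_row_normalization_forced_for_flagged_algorithms(self):
        for alg in ("svm", "mlp", "gaussian_process", "logistic_regression"):
            assert ModelConfig(algorithm=alg).normalize_rows
        for alg in ("random_forest", "decision_tree", "naive_bayes"):
            assert not ModelConfig(algorithm=alg).normalize_rows


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert all(v == 1.0 for v in m.values())

    def test_all_negative_on_imbalanced_truth(self):
        y_true = [1] + [0] * 4
        m = compute_metrics(y_true, [0] * 5)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["recall_1"] == 0.0
        assert m["f1_1"] == 0.0

    def test_hand_computed_confusion(self):
        # TP=3, FP=1, FN=2, TN=14
        y_true = [1] * 3 + [0] * 1 + [1] * 2 + [0] * 14
        y_pred = [1] * 3 + [1] * 1 + [0] * 2 + [0] * 14
        m = compute_metrics(y_true, y_pred)
        assert m["precision_1"] == pytest.approx(0.75)
        assert m["recall_1"] == pytest.approx(0.6)
        assert m["f1_1"] == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6), abs=1e-9)

    def test_empty_vectors_raise(self):
        with pytest.raises(ConfigError):
            compute_metrics([], [])


@pytest.fixture(scope="module")
def summary(small_table):
    config = ModelConfig(n_runs=4, n_estimators=50)
    return run_protocol(small_table, config, master_seed=0,
                        predict_table=small_table.head(20))


class TestRunProtocol:
    def test_vote_fractions_are_run_averages(self, summary):
        run_cols = [c for c in summary.votes.columns if c.startswith("run_")]
        assert len(run_cols) == 4
        expected = summary.votes[run_cols].mean(axis=1)
        np.testing.assert_allclose(summary.vote_fractions["vote_fraction"], expected)
        # fractions live on the 1/n_runs grid
        grid = summary.vote_fractions["vote_fraction"] * 4
        np.testing.assert_allclose(grid, np.round(grid))

    def test_metrics_have_mean_and_sd(self, summary):
        assert set(summary.mean) == set(summary.sd)
        assert all(v >= 0 for v in summary.sd.values())
        assert len(summary.per_run) == 4

    def test_single_run_has_zero_sd(self, small_table):
        config = ModelConfig(n_runs=1, n_estimators=20)
        s = run_protocol(small_table, config, master_seed=1)
        assert all(v == 0.0 for v in s.sd.values())

    def test_too_few_seeds_raises(self, small_table):
        config = ModelConfig(n_runs=5, seeds=[1, 2])
        with pytest.raises(ConfigError):
            run_protocol(small_table, config)

    def test_seed_derivation_is_stable(self):
        assert child_seed(42, "run0") == child_seed(42, "run0")
        assert child_seed(42, "run0") != child_seed(42, "run1")
        assert 0 <= child_seed(123456, "oversample") < 2**31


class TestPlantedMechanismRecovery:
    def test_charge_features_dominate_importances(self, small_table):
        # the planted rule lives in three charge windows; after the full
        # per-run pipeline, the top importance must be a charge column
        config = ModelConfig(n_runs=1, n_estimators=100)
        s = run_protocol(small_table, config, master_seed=0, keep_models=True)
        model = s.models[0]
        imp = pd.Series(model.estimator.feature_importances_, index=model.columns)
        rule_feats = {"hirshfeld_q_h", "chelpg_q_heavy", "mulliken_q_h",
                      "npa_q_h", "hirshfeld_q_heavy"}
        top3 = set(imp.sort_values(ascending=False).head(3).index)
        assert top3 & rule_feats
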