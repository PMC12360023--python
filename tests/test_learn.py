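"""Metrics, the threshold rule, cross-validation protocol and learners."""

import numpy as np
import pytest

from ccinfer.featurize import build_vocabulary, featurize_dataset
from ccinfer.fixtures import RandomGraphParams, generate_random, reference_molecule
from ccinfer.learn import (
    EvalProtocol,
    Hyperplane,
    balanced_accuracy,
    cross_validate,
    fold_indices,
    r_squared,
    select_threshold,
    train,
)

from _oracles import select_threshold_bruteforce


class TestMetrics:
    def test_perfect_fit_r2_is_one(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_mean_predictor_r2_is_zero(self):
        y = [0.0, 1.0, 2.0]
        assert r_squared(y, [1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_worked_r2(self):
        assert r_squared([0, 1, 2], [0, 0, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [1.0, 2.0])

    def test_perfect_bacc(self):
        assert balanced_accuracy([0, 1, 1, 0], [0, 1, 1, 0]) == pytest.approx(1.0)

    def test_all_positive_predictor(self):
        assert balanced_accuracy([1, 1, 0, 0], [1, 1, 1, 1]) == pytest.approx(0.5)

    def test_worked_confusion_counts(self):
        # TP=3 FN=1 TN=2 FP=2 -> (3/4 + 2/4) / 2
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        preds = [1, 1, 1, 0, 1, 1, 0, 0]
        assert balanced_accuracy(labels, preds) == pytest.approx(0.625)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([1, 1], [1, 0])


class TestSelectThreshold:
    def test_two_point_example_attains_perfect_tilde_bacc(self):
        # both candidates score 1 (TP~ uses >=, TN~ uses <=, so a point at r
        # counts as correct for both classes); ties break to the smallest r
        theta = select_threshold([0.1, 0.9], [0, 1])
        assert theta == pytest.approx(0.1)
        assert select_threshold_bruteforce([0.1, 0.9], [0, 1]) == pytest.approx(1.0)

    def test_separable_ties_break_to_smallest(self):
        # maximisers are r in {0.2, 0.8}; the smallest wins
        theta = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert theta == pytest.approx(0.2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_scan(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.normal(size=n), 3)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        theta = select_threshold(scores, labels)
        c1, c0 = (labels == 1).sum(), (labels == 0).sum()
        tp = ((labels == 1) & (scores >= theta)).sum()
        tn = ((labels == 0) & (scores <= theta)).sum()
        achieved = 0.5 * (tp / c1 + tn / c0)
        assert achieved == pytest.approx(select_threshold_bruteforce(scores, labels))


class TestFolds:
    @pytest.mark.parametrize("n,k", [(10, 5), (11, 5), (53, 5), (7, 3)])
    def test_fold_sizes_differ_by_at_most_one(self, n, k):
        folds = fold_indices(n, k, np.random.default_rng(0))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(n))


@pytest.fixture(scope="module")
def small_features():
    mols = [reference_molecule(n) for n in
            ("benzene", "catechol", "resorcinol", "hydroquinone",
             "spiro", "fused_bicyclic", "triple_shared_edge")]
    mols += [generate_random(RandomGraphParams(seed=s)) for s in range(23)]
    vocab = build_vocabulary(mols)
    df = featurize_dataset(mols, vocab, "2L+CC")
    return df[vocab.static_names + vocab.columns_cc()]


class TestTrain:
    def test_llr_recovers_noiseless_weights(self, small_features):
        # restrict to an identifiable (non-collinear) design
        X = small_features[["n_heavy", "n_interior", "bond_int_2", "deg_int_2"]]
        w_true = np.array([2.0, 0.0, -1.5, 0.0])
        y = X.to_numpy() @ w_true + 7.0
        model = train(X, y, "llr", "regression", hyperparams={"alphas": [1e-8]})
        assert np.max(np.abs(model.hyperplane.w - w_true)) <= 1e-3

    def test_llr_sparsifies_under_strong_penalty(self, small_features):
        X = small_features
        y = X["n_heavy"].to_numpy() * 2.0
        model = train(X, y, "llr", "regression", hyperparams={"alphas": [4.0]})
        assert np.sum(model.hyperplane.w == 0.0) > 0

    def test_dt_fits_separable_training_data(self, small_features):
        X = small_features.iloc[:10]
        y = (X["n_heavy"] > X["n_heavy"].median()).astype(int).to_numpy()
        model = train(X, y, "dt", "classification")
        assert balanced_accuracy(y, model.predict(X)) == pytest.approx(1.0)

    def test_nonfinite_features_rejected(self, small_features):
        X = small_features.copy()
        X.iloc[0, 0] = np.inf
        with pytest.raises(ValueError):
            train(X, np.zeros(len(X)), "llr", "regression")

    def test_hyperplane_json_roundtrip(self, small_features):
        X = small_features
        y = X["n_heavy"].to_numpy()
        plane = train(X, y, "llr", "regression").hyperplane
        again = Hyperplane.from_json(plane.to_json())
        assert np.allclose(again.w, plane.w) and again.b == pytest.approx(plane.b)
        assert np.allclose(again.score(X), plane.score(X))


class TestCrossValidate:
    def test_noiseless_linear_recovery_median_r2_one(self, small_features):
        X = small_features
        w = np.zeros(X.shape[1])
        w[list(X.columns).index("n_heavy")] = 2.0
        w[list(X.columns).index("n_interior")] = 0.5
        y = X.to_numpy() @ w + 3.0
        summary = cross_validate(X, y, "llr", "regression",
                                 EvalProtocol(n_repeats=2, seed=1))
        assert summary.median == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_reproduces_all_values(self, small_features):
        X = small_features
        y = X["n_heavy"].to_numpy() + 0.1 * X["bond_int_2"].to_numpy()
        a = cross_validate(X, y, "dt", "regression", EvalProtocol(n_repeats=2, seed=5))
        b = cross_validate(X, y, "dt", "regression", EvalProtocol(n_repeats=2, seed=5))
        assert a.values == b.values
        assert len(a.values) == 10

    def test_constant_targets_reported_per_fold(self, small_features):
        X = small_features
        y = np.full(len(X), 3.14)
        summary = cross_validate(X, y, "dt", "regression",
                                 EvalProtocol(n_repeats=1, seed=0))
        assert len(summary.errors) == 5
        assert np.isnan(summary.median)
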