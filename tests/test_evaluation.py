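"""Folds, SMOTE, grid search, AUC inference and the metric panel."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pronocase import evaluation as E


class TestStratifiedFolds:
    def test_imbalanced_cohort_fold_counts(self):
        y = np.array([1] * 38 + [0] * 281)
        folds = E.stratified_folds(y, 5, seed=0)
        for f in range(5):
            pos = np.sum(y[folds == f])
            assert pos in (7, 8)
        # each class spread within +-1 across folds
        for cls in (0, 1):
            counts = [np.sum((folds == f) & (y == cls)) for f in range(5)]
            assert max(counts) - min(counts) <= 1

    def test_balanced_exact_split(self):
        y = np.array([0, 1] * 10)
        folds = E.stratified_folds(y, 5, seed=1)
        for f in range(5):
            assert np.sum(folds == f) == 4
            assert np.sum(y[folds == f]) == 2

    def test_class_smaller_than_k_rejected(self):
        y = np.array([1, 1, 1] + [0] * 20)
        with pytest.raises(ValueError, match="stratified"):
            E.stratified_folds(y, 5, seed=0)

    def test_deterministic_given_seed(self):
        y = np.array([1] * 10 + [0] * 40)
        assert np.array_equal(
            E.stratified_folds(y, 5, 42), E.stratified_folds(y, 5, 42))


class TestSmote:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(3, 1, (19, 3))])
        self.y = np.array([0] * 50 + [1] * 19)

    def test_minority_doubled(self):
        Xa, ya = E.smote_oversample(self.X, self.y, E.SmoteConfig(seed=0))
        assert np.sum(ya == 1) == 38           # 19 original + 19 synthetic
        assert np.sum(ya == 0) == 50

    def test_majority_rows_untouched_and_dimension_kept(self):
        Xa, ya = E.smote_oversample(self.X, self.y, E.SmoteConfig(seed=0))
        assert Xa.shape[1] == self.X.shape[1]
        np.testing.assert_array_equal(Xa[: len(self.y)], self.X)
        np.testing.assert_array_equal(ya[: len(self.y)], self.y)

    def test_synthetic_points_in_minority_bounding_box(self):
        """Convex combinations of minority points cannot leave the class's
        axis-aligned bounding box."""
        for seed in range(5):
            Xa, ya = E.smote_oversample(self.X, self.y, E.SmoteConfig(seed=seed))
            synth = Xa[len(self.y):]
            Xm = self.X[self.y == 1]
            assert np.all(synth >= Xm.min(axis=0) - 1e-12)
            assert np.all(synth <= Xm.max(axis=0) + 1e-12)

    def test_zero_variance_minority_reproduces_itself(self):
        X = np.vstack([np.zeros((20, 2)), np.ones((8, 2)) * 7])
        y = np.array([0] * 20 + [1] * 8)
        Xa, ya = E.smote_oversample(X, y, E.SmoteConfig(seed=3))
        synth = Xa[len(y):]
        np.testing.assert_allclose(synth, 7.0)

    def test_multiplier_one_is_identity(self):
        Xa, ya = E.smote_oversample(
            self.X, self.y, E.SmoteConfig(minority_multiplier=1, seed=0))
        np.testing.assert_array_equal(Xa, self.X)

    def test_too_few_minority_members_rejected(self):
        X = np.vstack([np.zeros((20, 2)), np.ones((4, 2))])
        y = np.array([0] * 20 + [1] * 4)
        with pytest.raises(ValueError, match="smaller k"):
            E.smote_oversample(X, y, E.SmoteConfig(k=5))

    def test_deterministic_given_seed(self):
        a = E.smote_oversample(self.X, self.y, E.SmoteConfig(seed=9))
        b = E.smote_oversample(self.X, self.y, E.SmoteConfig(seed=9))
        np.testing.assert_array_equal(a[0], b[0])


class TestAucInference:
    def test_perfect_separation(self):
        auc, ci, p = E.auc_with_inference(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0 and ci[1] == 1.0

    def test_all_scores_tied_gives_half(self):
        auc, _, p = E.auc_with_inference(np.full(30, 0.5),
                                         np.array([1] * 10 + [0] * 20))
        assert auc == 0.5 and p == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            E.auc_with_inference(np.array([0.1, 0.9]), np.array([1, 1]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pair_counting_oracle(self, seed):
        """AUC equals (concordant + ties/2) / (positives * negatives),
        counted by brute force over all pairs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (len(pos) * len(neg))
        auc, _, _ = E.auc_with_inference(scores, labels)
        assert auc == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.array([0, 1] * 20)
        a1, _, _ = E.auc_with_inference(scores, labels)
        a2, _, _ = E.auc_with_inference(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestConfusionMetrics:
    def test_published_panel_reconstruction(self):
        """Counts rebuilt from sensitivity 66.6% / specificity 47.4% with
        class sizes 281/38 (majority positive) reproduce the published
        accuracy, PPV and NPV to one decimal, and pin the exact F1 those
        counts imply."""
        tp, fp, tn, fn = E.counts_from_rates(0.666, 0.474, 281, 38)
        assert (tp, fp, tn, fn) == (187, 20, 18, 94)
        panel = E.confusion_metrics(tp, fp, tn, fn)
        assert round(100 * panel["accuracy"], 1) == 64.3
        assert round(100 * panel["ppv"], 1) == 90.3
        assert round(100 * panel["npv"], 1) == 16.1
        assert panel["f1"] == pytest.approx(2 * 187 / (2 * 187 + 20 + 94))

    def test_symmetric_counts_give_all_half(self):
        panel = E.confusion_metrics(1, 1, 1, 1)
        assert all(panel[k] == 0.5 for k in
                   ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1"))

    def test_error_free_counts(self):
        panel = E.confusion_metrics(5, 0, 10, 0)
        assert panel["accuracy"] == 1.0 and panel["f1"] == 1.0

    def test_zero_denominator_reported_absent(self):
        panel = E.confusion_metrics(0, 0, 5, 5)
        assert panel["ppv"] is None and panel["sensitivity"] == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            E.confusion_metrics(-1, 0, 0, 1)


class _OracleModel:
    """Backend that scores every sample with its true label (test double):
    built from the full dataset so held-out rows are scored perfectly."""

    def __init__(self, X_full, y_full):
        self._lookup = {
            row.tobytes(): float(lab) for row, lab in zip(X_full, y_full)
        }

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.array([self._lookup[row.tobytes()] for row in X], float)
        return np.column_stack([1 - p, p])


class TestGridSearch:
    def make_data(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 2)) + 2.5 * y[:, None]
        return X, y

    def test_one_point_grid_returns_it(self):
        X, y = self.make_data()
        spec = E.ClassifierSpec("logistic_regression", {"C": (1.0,)})
        assert E.grid_search(spec, X, y) == {"C": 1.0}

    def test_duplicated_grid_point_first_occurrence_wins(self):
        X, y = self.make_data()
        spec = E.ClassifierSpec("logistic_regression", {"C": (1.0, 1.0)})
        # both points tie exactly; declaration order breaks the tie
        best = E.grid_search(spec, X, y)
        assert best == {"C": 1.0}

    def test_selects_hyperparameter_matching_data_structure(self):
        # XOR-structured classes: a depth-1 stump cannot rank them
        # (AUC ~ 0.5) while a depth-3 tree separates them
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], float)
        X = np.vstack([
            centers[i] + rng.normal(0, 0.05, (40, 2)) for i in range(4)
        ])
        y = np.array([0] * 80 + [1] * 80)
        spec = E.ClassifierSpec("decision_tree", {"max_depth": (1, 3)})
        assert E.grid_search(spec, X, y, seed=1) == {"max_depth": 3}

    def test_empty_grid_entry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            E.ClassifierSpec("logistic_regression", {"C": ()})

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            E.ClassifierSpec("perceptron", {})


class TestCrossValidate:
    def make_data(self, seed=0, n=150, informative=True):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.25).astype(int)
        shift = 2.0 if informative else 0.0
        X = rng.normal(size=(n, 3)) + shift * y[:, None]
        return X, y

    def test_oracle_scorer_achieves_perfect_metrics(self):
        X, y = self.make_data(seed=4)

        class OracleSpec(E.ClassifierSpec):
            def build(self, params, seed):
                return _OracleModel(X, y)

        spec = OracleSpec("logistic_regression", {"C": (1.0,)})
        cv = E.CVConfig(positive_class="suicidal", seed=0)
        report = E.cross_validate(X, y, spec, cv, smote=None)
        assert report.auc == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_pooled_counts_sum_to_cohort_size(self):
        X, y = self.make_data(seed=1)
        report = E.cross_validate(
            X, y, E.ClassifierSpec("logistic_regression", {"C": (1.0,)}),
            E.CVConfig(seed=3), E.SmoteConfig(seed=3))
        assert report.tp + report.fp + report.tn + report.fn == len(y)

    def test_deterministic_given_seed(self):
        X, y = self.make_data(seed=2)
        args = (X, y, E.ClassifierSpec("logistic_regression", {"C": (0.1, 1.0)}),
                E.CVConfig(seed=11), E.SmoteConfig(seed=11))
        assert E.cross_validate(*args).as_dict() == E.cross_validate(*args).as_dict()

    def test_null_data_auc_near_half(self):
        X, y = self.make_data(seed=6, informative=False)
        report = E.cross_validate(
            X, y, E.ClassifierSpec("logistic_regression", {"C": (1.0,)}),
            E.CVConfig(seed=0), E.SmoteConfig(seed=0))
        assert report.auc_ci[0] <= 0.5 <= report.auc_ci[1]

    def test_positive_class_flip_swaps_sensitivity_and_specificity(self):
        X, y = self.make_data(seed=8)
        spec = E.ClassifierSpec("logistic_regression", {"C": (1.0,)})
        maj = E.cross_validate(X, y, spec, E.CVConfig(seed=2), None)
        mino = E.cross_validate(
            X, y, spec, E.CVConfig(seed=2, positive_class="suicidal"), None)
        assert maj.sensitivity == pytest.approx(mino.specificity)
        assert maj.specificity == pytest.approx(mino.sensitivity)
        assert maj.auc == pytest.approx(mino.auc, abs=1e-12)

    @pytest.mark.parametrize("family", sorted(E.MODEL_FAMILIES))
    def test_every_model_family_runs(self, family):
        X, y = self.make_data(seed=9, n=80)
        spec = E.ClassifierSpec(
            family, {k: v[:1] for k, v in E.MODEL_FAMILIES[family].items()})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = E.cross_validate(X, y, spec, E.CVConfig(seed=1),
                                      E.SmoteConfig(seed=1, k=3))
        assert 0.0 <= report.auc <= 1.0
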