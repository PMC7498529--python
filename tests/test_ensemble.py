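"""KNN classification, cross-validation, ranking and majority voting."""

import numpy as np
import pytest
from scipy import stats

from eegvote.ensemble import (
    ChannelEvaluation, CVConfig, KNNConfig, channel_oof_predictions,
    compute_metrics, knn_fit_predict, majority_vote, make_folds,
    rank_channels, rhythm_vote, two_step_pipeline,
)
from eegvote.errors import ConfigError, DataError
from eegvote.recording import ALPHA, HIGH, LOW, TrialDataset, standard_bands


def oracle_knn(train_X, train_y, test_X, k, p=2.0, standardize=True):
    """Exhaustive distance-sort KNN: full Minkowski distance matrix, stable
    sort by (distance, training index), majority of the first k."""
    train_X, test_X = np.asarray(train_X, float), np.asarray(test_X, float)
    if standardize:
        mu, sd = train_X.mean(0), train_X.std(0)
        sd = np.where(sd > 0, sd, 1.0)
        train_X, test_X = (train_X - mu) / sd, (test_X - mu) / sd
    preds = []
    for t in test_X:
        d = (np.abs(train_X - t) ** p).sum(axis=1) ** (1 / p)
        order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
        votes = [train_y[i] for i in order]
        n_high = votes.count(HIGH)
        if n_high * 2 == k:
            preds.append(votes[0])
        else:
            preds.append(HIGH if n_high * 2 > k else LOW)
    return np.array(preds)


def separable_features(rng, n_trials=30, n_features=5, gap=10.0, noise=0.1):
    y = np.array([HIGH, LOW] * (n_trials // 2))
    X = rng.standard_normal((n_trials, n_features)) * noise
    X[y == HIGH] += gap
    return X, y


class TestKNN:
    def test_coincident_point_takes_its_class(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([LOW, HIGH])
        assert knn_fit_predict(X, y, [[0.0, 0.0]], KNNConfig(k=1))[0] == LOW

    def test_self_prediction_is_perfect_at_k1(self, rng):
        X, y = separable_features(rng)
        preds = knn_fit_predict(X, y, X, KNNConfig(k=1))
        np.testing.assert_array_equal(preds, y)

    def test_matches_exhaustive_oracle_on_random_problems(self, rng):
        for _ in range(25):
            X = rng.standard_normal((30, 2))
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            T = rng.standard_normal((10, 2))
            got = knn_fit_predict(X, y, T, KNNConfig(k=3))
            np.testing.assert_array_equal(got, oracle_knn(X, y, T, 3))

    def test_unstandardized_mode_matches_oracle(self, rng):
        X = rng.standard_normal((20, 3)) * [1, 100, 0.01]
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        T = rng.standard_normal((6, 3)) * [1, 100, 0.01]
        cfg = KNNConfig(k=3, standardize=False)
        np.testing.assert_array_equal(
            knn_fit_predict(X, y, T, cfg),
            oracle_knn(X, y, T, 3, standardize=False))

    def test_configuration_errors(self, rng):
        X, y = separable_features(rng, n_trials=4)
        with pytest.raises(ConfigError):
            knn_fit_predict(X, y, X, KNNConfig(k=5))
        with pytest.raises(ConfigError):
            knn_fit_predict(X, np.zeros(4, dtype=int), X, KNNConfig(k=1))
        with pytest.raises(DataError):
            knn_fit_predict(X, y, X[:, :2], KNNConfig(k=1))


class TestFolds:
    def test_eighty_trials_make_ten_folds_of_eight(self):
        labels = np.array([HIGH, LOW] * 40)
        folds = make_folds(80, labels, CVConfig(n_folds=10, seed=3))
        ids, counts = np.unique(folds, return_counts=True)
        assert list(ids) == list(range(10))
        assert np.all(counts == 8)

    def test_same_seed_reproduces_assignment(self):
        labels = np.array([HIGH, LOW] * 25)
        a = make_folds(50, labels, CVConfig(seed=9))
        b = make_folds(50, labels, CVConfig(seed=9))
        np.testing.assert_array_equal(a, b)
        c = make_folds(50, labels, CVConfig(seed=10))
        assert not np.array_equal(a, c)

    def test_partition_is_complete_and_disjoint(self):
        labels = np.array([HIGH] * 33 + [LOW] * 29)
        folds = make_folds(62, labels, CVConfig(n_folds=10, seed=0))
        assert folds.shape == (62,)
        assert set(np.unique(folds)) == set(range(10))

    def test_stratification_balances_classes_within_one(self):
        labels = np.array([HIGH] * 40 + [LOW] * 40)
        folds = make_folds(80, labels, CVConfig(n_folds=10, seed=1))
        for f in range(10):
            in_fold = labels[folds == f]
            assert abs((in_fold == HIGH).sum() - 4) <= 1

    def test_small_class_falls_back_with_warning(self):
        labels = np.array([HIGH] * 3 + [LOW] * 27)
        with pytest.warns(RuntimeWarning):
            folds = make_folds(30, labels, CVConfig(n_folds=10, seed=0))
        assert folds.shape == (30,)

    def test_more_folds_than_trials_rejected(self):
        with pytest.raises(ConfigError):
            make_folds(5, np.array([0, 1] * 2 + [0]), CVConfig(n_folds=10))


class TestChannelEvaluation:
    def test_separable_features_classified_perfectly(self, rng):
        X, y = separable_features(rng, n_trials=40)
        ev = channel_oof_predictions(X, y, cv=CVConfig(seed=2))
        assert ev.accuracy == 1.0
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_shuffled_labels_stay_at_chance(self, rng):
        X, _ = separable_features(rng, n_trials=40)
        y = rng.permutation([HIGH, LOW] * 20)
        ev = channel_oof_predictions(X, y, cv=CVConfig(seed=2))
        lo, hi = stats.binom.ppf([0.005, 0.995], 40, 0.5) / 40
        assert lo <= ev.accuracy <= hi

    def test_deterministic_given_seeds(self, rng):
        X, y = separable_features(rng, n_trials=30, gap=0.5, noise=1.0)
        a = channel_oof_predictions(X, y, cv=CVConfig(seed=5))
        b = channel_oof_predictions(X, y, cv=CVConfig(seed=5))
        np.testing.assert_array_equal(a.oof_predictions, b.oof_predictions)

    def test_out_of_fold_discipline_under_poisoning(self, rng):
        """Corrupting one trial's features must not move predictions of the
        other trials in its own fold (their model never saw it)."""
        X, y = separable_features(rng, n_trials=30, gap=1.0, noise=1.0)
        cv = CVConfig(seed=4)
        folds = make_folds(30, y, cv)
        base = channel_oof_predictions(X, y, cv=cv, folds=folds)
        poisoned = X.copy()
        poisoned[0] += 1e4
        after = channel_oof_predictions(poisoned, y, cv=cv, folds=folds)
        same_fold = (folds == folds[0]) & (np.arange(30) != 0)
        np.testing.assert_array_equal(
            base.oof_predictions[same_fold], after.oof_predictions[same_fold])


class TestRanking:
    @staticmethod
    def make_eval(i, acc, sens=0.5):
        return ChannelEvaluation(
            channel=f"ch{i}", rhythm="alpha", channel_index=i,
            oof_predictions=np.zeros(4, dtype=int), accuracy=acc,
            sensitivity=sens, specificity=0.5)

    def test_descending_accuracy_selection(self):
        evals = [self.make_eval(0, 0.6), self.make_eval(1, 0.9),
                 self.make_eval(2, 0.7)]
        top = rank_channels(evals, 2)
        assert [e.channel_index for e in top] == [1, 2]

    def test_accuracy_ties_broken_by_sensitivity_then_order(self):
        evals = [self.make_eval(0, 0.7, sens=0.5),
                 self.make_eval(1, 0.7, sens=0.9),
                 self.make_eval(2, 0.7, sens=0.5)]
        top = rank_channels(evals, 3)
        assert [e.channel_index for e in top] == [1, 0, 2]

    def test_all_equal_keeps_recording_order(self):
        evals = [self.make_eval(i, 0.5) for i in range(6)]
        assert [e.channel_index for e in rank_channels(evals, 4)] == [0, 1, 2, 3]

    def test_n_top_equal_to_all_is_a_permutation(self):
        evals = [self.make_eval(i, acc)
                 for i, acc in enumerate([0.3, 0.9, 0.1, 0.6])]
        top = rank_channels(evals, 4)
        assert sorted(e.channel_index for e in top) == [0, 1, 2, 3]

    def test_too_many_requested_rejected(self):
        with pytest.raises(ConfigError):
            rank_channels([self.make_eval(0, 0.5)], 2)


class TestMajorityVote:
    def test_column_majority(self):
        votes = np.array([[1], [1], [0], [0], [1]])
        assert majority_vote(votes)[0] == 1

    def test_single_voter_is_identity(self, rng):
        row = rng.integers(0, 2, size=(1, 20))
        np.testing.assert_array_equal(majority_vote(row), row[0])

    def test_odd_voter_permutation_invariance(self, rng):
        votes = rng.integers(0, 2, size=(5, 40))
        base = majority_vote(votes)
        for _ in range(10):
            perm = rng.permutation(5)
            np.testing.assert_array_equal(majority_vote(votes[perm]), base)

    def test_matches_bruteforce_mode(self, rng):
        for _ in range(50):
            votes = rng.integers(0, 2, size=(rng.integers(1, 8),
                                             rng.integers(1, 30)))
            got = majority_vote(votes)
            for j in range(votes.shape[1]):
                col = list(votes[:, j])
                n1, n0 = col.count(1), col.count(0)
                expected = col[0] if n1 == n0 else int(n1 > n0)
                assert got[j] == expected

    def test_even_tie_goes_to_first_voter(self):
        votes = np.array([[1, 0], [0, 1], [0, 1], [1, 0]])
        np.testing.assert_array_equal(majority_vote(votes), [1, 0])

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError):
            majority_vote(np.empty((0, 0)))


class TestMetrics:
    def test_confusion_counts(self):
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        preds = np.array([1, 1, 1, 0, 0, 0, 1, 1])
        acc, sens, spec = compute_metrics(preds, truth)
        assert (acc, sens, spec) == (0.625, 0.75, 0.5)

    def test_perfect_and_inverted_predictions(self):
        truth = np.array([1, 0, 1, 0])
        assert compute_metrics(truth, truth) == (1.0, 1.0, 1.0)
        assert compute_metrics(1 - truth, truth) == (0.0, 0.0, 0.0)

    def test_single_class_truth_marks_undefined_rate(self):
        truth = np.ones(4, dtype=int)
        acc, sens, spec = compute_metrics(np.array([1, 1, 0, 1]), truth)
        assert acc == 0.75 and sens == 0.75 and np.isnan(spec)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            compute_metrics(np.zeros(3), np.zeros(4))


class TestPipeline:
    def test_rhythm_vote_with_single_channel_equals_its_predictions(
            self, small_effect_dataset):
        ds = small_effect_dataset
        rv = rhythm_vote(ds, ALPHA, cv=CVConfig(seed=1), n_top=1)
        best = rv.top_channel_indices[0]
        best_eval = rv.channel_evaluations[best]
        np.testing.assert_array_equal(rv.predictions, best_eval.oof_predictions)

    def test_four_bands_duplicate_best_rhythm_for_odd_vote(
            self, small_effect_dataset):
        res = two_step_pipeline(small_effect_dataset, cv=CVConfig(seed=1),
                                n_top=3)
        assert res.duplicated_rhythm in [b.name for b in standard_bands()]

    def test_three_bands_need_no_duplication(self, small_effect_dataset):
        bands = standard_bands()[:3]
        res = two_step_pipeline(small_effect_dataset, bands, cv=CVConfig(seed=1),
                                n_top=3)
        assert res.duplicated_rhythm is None

    def test_single_band_single_channel_reduces_to_channel_cv(
            self, small_effect_dataset):
        ds = small_effect_dataset
        one = TrialDataset(data=ds.data[:, :1], fs=ds.fs,
                           channel_names=ds.channel_names[:1],
                           labels=ds.labels, trial_ids=ds.trial_ids)
        cv = CVConfig(seed=6)
        res = two_step_pipeline(one, [ALPHA], cv=cv, n_top=1)
        from eegvote.ensemble import dataset_features
        feats = dataset_features(one, [ALPHA])[:, 0, 0]
        folds = make_folds(one.n_trials, one.labels, cv)
        ev = channel_oof_predictions(feats, one.labels, cv=cv, folds=folds)
        np.testing.assert_array_equal(res.final_predictions, ev.oof_predictions)
        assert res.accuracy == ev.accuracy
        assert res.duplicated_rhythm is None

    def test_pipeline_deterministic_bitwise(self, small_effect_dataset):
        a = two_step_pipeline(small_effect_dataset, cv=CVConfig(seed=3), n_top=3)
        b = two_step_pipeline(small_effect_dataset, cv=CVConfig(seed=3), n_top=3)
        np.testing.assert_array_equal(a.final_predictions, b.final_predictions)
        assert a.to_dict() == b.to_dict()

    def test_reported_proportions_have_one_over_n_granularity(
            self, small_effect_dataset):
        res = two_step_pipeline(small_effect_dataset, cv=CVConfig(seed=3),
                                n_top=3)
        n = small_effect_dataset.n_trials
        for rv in res.per_rhythm.values():
            assert (rv.accuracy * n) == pytest.approx(round(rv.accuracy * n))
        assert (res.accuracy * n) == pytest.approx(round(res.accuracy * n))

    def test_effect_channels_selected_on_effect_rhythm(
            self, small_effect_dataset):
        rv = rhythm_vote(small_effect_dataset, ALPHA, cv=CVConfig(seed=2),
                         n_top=2)
        assert set(rv.top_channel_indices) == {1, 4}

    def test_unlabeled_dataset_rejected(self, small_effect_dataset):
        ds = small_effect_dataset
        unlabeled = TrialDataset(data=ds.data, fs=ds.fs,
                                 channel_names=ds.channel_names)
        with pytest.raises(ConfigError):
            two_step_pipeline(unlabeled, cv=CVConfig(seed=0))

    def test_nested_selection_removes_optimism_on_null(
            self, small_null_dataset):
        """With channel selection inside each training fold, a label-free
        dataset is classified at chance level."""
        res = two_step_pipeline(small_null_dataset, cv=CVConfig(seed=5),
                                n_top=3, nested_selection=True)
        n = small_null_dataset.n_trials
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5) / n
        assert lo <= res.accuracy <= hi
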