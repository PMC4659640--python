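import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lesionfield import (
    ClassificationRun,
    ConfigurationError,
    NumericalError,
    PairingError,
    SchemaError,
    compare_runs_paired,
    evaluate_once,
    random_chance,
    repeat_performance,
    stratified_split,
    subset_search,
)
from lesionfield.classifier import make_splits, splits_digest


def labels_of(n_sig, n_poor):
    return np.array(["significant"] * n_sig + ["poor"] * n_poor)


class TestRandomChance:
    @pytest.mark.parametrize(
        "n_sig, n_poor, expected",
        [(20, 15, 20 / 35), (10, 10, 0.5), (13, 19, 19 / 32), (13, 16, 16 / 29)],
    )
    def test_majority_fraction(self, n_sig, n_poor, expected):
        assert random_chance(labels_of(n_sig, n_poor)) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(NumericalError):
            random_chance(labels_of(5, 0))


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "n_sig, n_poor, want_train",
        [(10, 10, (7, 7)), (20, 15, (14, 11)), (2, 30, (1, 21))],
    )
    def test_round_half_up_per_class(self, n_sig, n_poor, want_train, rng):
        y = labels_of(n_sig, n_poor)
        train, test = stratified_split(y, 0.7, rng)
        ytr = y[train]
        assert (np.sum(ytr == "significant"), np.sum(ytr == "poor")) == want_train
        # partition bookkeeping
        assert len(set(train) | set(test)) == len(y)
        assert set(train).isdisjoint(test)
        # both folds keep both classes
        assert set(np.unique(y[test])) == {"significant", "poor"}

    def test_tiny_class_clamped(self, rng):
        y = labels_of(2, 5)
        train, test = stratified_split(y, 0.9, rng)
        assert np.sum(y[train] == "significant") == 1
        assert np.sum(y[test] == "significant") == 1

    def test_singleton_class_rejected(self, rng):
        with pytest.raises(SchemaError):
            stratified_split(labels_of(1, 5), rng=rng)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_split(labels_of(5, 5), train_frac=1.0)

    def test_seeded_reproducibility(self):
        y = labels_of(12, 9)
        a = stratified_split(y, rng=np.random.default_rng(3))
        b = stratified_split(y, rng=np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestEvaluateOnce:
    def test_separable_feature_perfect(self, rng):
        y = labels_of(10, 10)
        x = np.where(y == "significant", 5.0, -5.0) + rng.normal(0, 0.1, 20)
        split = stratified_split(y, rng=rng)
        assert evaluate_once(x, y, split) == 1.0

    def test_constant_feature_degenerates_to_majority(self, rng):
        """With no usable feature the classifier predicts the training
        majority class, scoring the test-fold majority fraction."""
        y = labels_of(20, 15)
        x = np.ones(35)
        split = stratified_split(y, 0.7, rng)
        with pytest.warns(UserWarning):
            acc = evaluate_once(x, y, split)
        test_y = y[split[1]]
        assert acc == pytest.approx(np.mean(test_y == "significant"))

    def test_uninformative_features_score_near_chance(self, rng):
        """Null simulation: labels independent of features."""
        y = labels_of(15, 15)
        accs = []
        for _ in range(300):
            x = rng.normal(size=(30, 3))
            accs.append(evaluate_once(x, y, stratified_split(y, rng=rng)))
        accs = np.array(accs)
        se = accs.std(ddof=1) / math.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * se + 1e-9

    def test_agrees_with_public_estimator_pipeline(self, rng):
        """The accuracy path must equal an independently assembled
        standardise-then-SVC evaluation on random problems."""
        from sklearn.svm import SVC

        for _ in range(25):
            n = int(rng.integers(14, 40))
            k = int(rng.integers(1, 5))
            X = rng.normal(size=(n, k))
            y = np.where(rng.random(n) < 0.5, "significant", "poor")
            if len(set(y)) < 2 or min(np.sum(y == "poor"), np.sum(y == "significant")) < 2:
                continue
            split = stratified_split(y, rng=rng)
            tr, te = split
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            if np.any(sd == 0):
                continue
            clf = SVC(kernel="linear", C=1.0)
            clf.fit((X[tr] - mu) / sd, y[tr])
            ref = np.mean(clf.predict((X[te] - mu) / sd) == y[te])
            assert evaluate_once(X, y, split) == pytest.approx(float(ref))

    def test_zero_columns_rejected(self, rng):
        y = labels_of(5, 5)
        with pytest.raises(SchemaError):
            evaluate_once(np.empty((10, 0)), y, stratified_split(y, rng=rng))


class TestRepeatPerformance:
    def test_separable_run_hits_ceiling_with_inf_t(self, rng):
        y = labels_of(12, 10)
        x = np.where(y == "significant", 3.0, -3.0) + rng.normal(0, 0.05, 22)
        run = repeat_performance(x, y, n_repeats=20, seed=0)
        assert run.mean == 1.0 and run.sd == 0.0
        assert run.t_score == math.inf and run.p_value == 0.0

    def test_same_seed_identical_vectors(self, cohort35):
        r = cohort35.records
        a = repeat_performance(
            r[["reil_lingual"]], r["label_hemi"], n_repeats=15, seed=7
        )
        b = repeat_performance(
            r[["reil_lingual"]], r["label_hemi"], n_repeats=15, seed=7
        )
        assert np.array_equal(a.accuracies, b.accuracies)
        assert a.split_digest == b.split_digest

    def test_t_score_formula(self):
        run = ClassificationRun(
            accuracies=np.array([0.6, 0.7, 0.8, 0.7]),
            chance=0.5,
            split_digest="x",
        )
        sd = np.std([0.6, 0.7, 0.8, 0.7], ddof=1)
        assert run.t_score == pytest.approx((0.7 - 0.5) / (sd / 2.0))


class TestSubsetSearch:
    def test_single_candidate_is_best(self, cohort35):
        r = cohort35.records
        res = subset_search(
            r, r["label_hemi"], columns=["lesion_volume_ml"], n_repeats=10, seed=1
        )
        assert res.best_subset == ("lesion_volume_ml",)
        assert len(res.all_results) == 1

    def test_matches_independent_enumeration(self, cohort35):
        """Brute-force oracle over M=4: same subsets, t-scores and the
        same argmax under the tie rule."""
        r = cohort35.records
        cols = ["reil_calcarine", "reil_lingual", "age", "lesion_volume_ml"]
        y = r["label_hemi"]
        splits = make_splits(y, 8, 0.7, seed=3)
        res = subset_search(r, y, columns=cols, splits=splits)
        assert len(res.all_results) == 2**4 - 1

        chance = random_chance(y)
        best_key, best_subset = None, None
        for k in range(1, 5):
            for combo in itertools.combinations(cols, k):
                accs = np.array(
                    [
                        evaluate_once(r[list(combo)], y, sp)
                        for sp in splits
                    ]
                )
                sd = accs.std(ddof=1)
                t = (
                    math.inf
                    if sd == 0 and accs.mean() > chance
                    else (accs.mean() - chance) / (sd / math.sqrt(len(accs)))
                )
                row = res.all_results[res.all_results["subset"] == combo]
                assert row["t_score"].iloc[0] == pytest.approx(t)
                key = (-t, k, combo)
                if best_key is None or key < best_key:
                    best_key, best_subset = key, combo
        assert res.best_subset == best_subset

    def test_common_random_numbers_across_runs(self, cohort35):
        r = cohort35.records
        y = r["label_hemi"]
        a = subset_search(r, y, columns=["age"], n_repeats=12, seed=9)
        b = subset_search(
            r, y, columns=["reil_calcarine", "reil_cuneus"], n_repeats=12, seed=9
        )
        assert a.best_run.split_digest == b.best_run.split_digest

    def test_best_t_at_least_single_features(self, cohort35):
        r = cohort35.records
        y = r["label_hemi"]
        cols = ["reil_calcarine", "reil_lingual", "reil_cuneus"]
        res = subset_search(r, y, columns=cols, n_repeats=12, seed=5)
        singles = res.all_results[res.all_results["n_features"] == 1]
        assert res.best_run.t_score >= singles["t_score"].max() - 1e-12

    def test_planted_feature_recovered(self, rng):
        """A single informative feature among noise lands in the best
        subset in at least 80 % of replicates."""
        hits = 0
        reps = 50
        for _ in range(reps):
            y = labels_of(18, 18)
            signal = (y == "significant").astype(float) + rng.normal(0, 0.8, 36)
            X = pd.DataFrame(
                {
                    "signal": signal,
                    "n1": rng.normal(size=36),
                    "n2": rng.normal(size=36),
                    "n3": rng.normal(size=36),
                }
            )
            res = subset_search(
                X, y, n_repeats=12, seed=int(rng.integers(2**31))
            )
            hits += "signal" in res.best_subset
        assert hits / reps >= 0.8

    def test_guard_on_feature_count(self, cohort35):
        r = cohort35.records
        too_many = pd.DataFrame(
            np.random.default_rng(0).normal(size=(35, 21)),
            columns=[f"c{i}" for i in range(21)],
        )
        with pytest.raises(ConfigurationError):
            subset_search(too_many, r["label_hemi"], n_repeats=5, seed=0)


class TestPairedComparison:
    def make_run(self, accs, digest="d"):
        return ClassificationRun(
            accuracies=np.asarray(accs), chance=0.5, split_digest=digest
        )

    def test_identical_runs(self):
        a = self.make_run([0.6, 0.7, 0.8])
        cmp_ = compare_runs_paired(a, a)
        assert cmp_.t_statistic == 0.0 and cmp_.p_value == 1.0

    def test_constant_shift_gives_inf_sentinel(self):
        a = self.make_run([0.60, 0.70, 0.80, 0.65])
        b = self.make_run([0.55, 0.65, 0.75, 0.60])
        cmp_ = compare_runs_paired(a, b)
        assert cmp_.t_statistic == math.inf and cmp_.p_value == 0.0

    def test_hand_computed_five_pairs(self):
        d = np.array([0.1, 0.05, 0.0, -0.05, 0.2])
        a = self.make_run(0.5 + d)
        b = self.make_run(np.full(5, 0.5))
        cmp_ = compare_runs_paired(a, b, n_comparisons=3)
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(5))
        assert cmp_.t_statistic == pytest.approx(t_oracle)
        from scipy import stats

        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=4)
        assert cmp_.p_value == pytest.approx(p_oracle)
        assert cmp_.p_bonferroni == pytest.approx(min(1.0, 3 * p_oracle))

    def test_mismatched_splits_rejected(self):
        a = self.make_run([0.6, 0.7], digest="d1")
        b = self.make_run([0.6, 0.7], digest="d2")
        with pytest.raises(PairingError):
            compare_runs_paired(a, b)

    def test_noise_features_do_not_change_splits(self, cohort35):
        r = cohort35.records.copy()
        y = r["label_hemi"]
        base = repeat_performance(r[["reil_lingual"]], y, n_repeats=10, seed=2)
        r["noise"] = np.random.default_rng(0).normal(size=len(r))
        more = repeat_performance(r[["reil_lingual", "noise"]], y, n_repeats=10, seed=2)
        assert base.split_digest == more.split_digest

    def test_digest_sensitive_to_split_change(self):
        y = labels_of(8, 8)
        s1 = make_splits(y, 5, seed=1)
        s2 = make_splits(y, 5, seed=2)
        assert splits_digest(s1) != splits_digest(s2)
        assert splits_digest(s1) == splits_digest(make_splits(y, 5, seed=1))
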