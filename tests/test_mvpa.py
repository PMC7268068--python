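"""Decoding core: z-scoring, fold construction, SVM accuracy, permutation chance."""

import numpy as np
import pandas as pd
import pytest

from fearpattern import SynthParams, make_pattern_basis, simulate_betas
from fearpattern.mvpa import (
    ClassifierSpec,
    FoldSpec,
    _fit_decision,
    cross_decode,
    decode_condition,
    decode_participant,
    excess_accuracy,
    make_running_index_folds,
    permutation_chance,
    subsample_ns,
    zscore_across_trials,
)


def imbalanced_labels(n_major=24, n_minor=12, rng=None):
    """Chronologically interleaved 2:1 labels, as in the retained CS condition."""
    rng = np.random.default_rng(rng)
    labels = np.array(["A"] * n_major + ["B"] * n_minor)
    return labels[rng.permutation(len(labels))]


class TestZscore:
    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        X = rng.normal(loc=3.0, scale=2.0, size=(40, 7))
        Z = zscore_across_trials(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        Z = zscore_across_trials(rng.normal(size=(30, 4)))
        assert np.allclose(zscore_across_trials(Z), Z, atol=1e-10)

    def test_constant_voxel_zeroed_with_warning(self):
        X = np.random.default_rng(2).normal(size=(20, 3))
        X[:, 1] = 5.0
        with pytest.warns(RuntimeWarning, match="constant voxel"):
            Z = zscore_across_trials(X)
        assert np.all(Z[:, 1] == 0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            zscore_across_trials(np.zeros((1, 3)))


class TestRunningIndexFolds:
    def test_modulo_rule_on_six_trials(self):
        labels = ["x"] * 6
        folds = make_running_index_folds(labels)
        assert list(folds[0].test) == [0, 3]
        assert list(folds[1].test) == [1, 4]
        assert list(folds[2].test) == [2, 5]

    def test_cs_condition_fold_sizes(self):
        labels = imbalanced_labels(24, 12, rng=3)
        folds = make_running_index_folds(labels)
        for f in folds:
            assert len(f.train) == 24
            assert len(f.test) == 12
            # per-fold class composition: 8 of the majority, 4 of the minority
            assert (labels[f.test] == "A").sum() == 8
            assert (labels[f.test] == "B").sum() == 4

    def test_test_sets_partition_trials(self):
        labels = imbalanced_labels(24, 12, rng=4)
        folds = make_running_index_folds(labels)
        pooled = np.concatenate([f.test for f in folds])
        assert sorted(pooled) == list(range(36))
        for f in folds:
            assert set(f.train).isdisjoint(f.test)

    def test_too_few_trials_of_a_stimulus_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            make_running_index_folds(["a", "a", "a", "b", "b"])


class TestDecodeCondition:
    def test_separable_data_decoded_perfectly(self):
        rng = np.random.default_rng(5)
        labels = imbalanced_labels(24, 12, rng=5)
        X = np.where(labels == "A", -1.0, 1.0)[:, None] + 0.01 * rng.normal(size=(36, 1))
        acc = decode_condition(X, labels, make_running_index_folds(labels))
        assert acc == 1.0

    def test_hand_computed_margin_example(self):
        # training: three points per class at x = -/+ 1; max-margin boundary x = 0.
        # test points at x = -0.5 (true a), 0.4 (true b), -0.1 (true b):
        # predictions a, b, a -> 2 of 3 correct.
        X = np.array(
            [[-1.0, 0.3], [-1.0, -0.3], [-1.0, 0.0], [1.0, 0.3], [1.0, -0.3], [1.0, 0.0],
             [-0.5, 0.0], [0.4, 0.0], [-0.1, 0.0]]
        )
        labels = np.array(["a", "a", "a", "b", "b", "b", "a", "b", "b"])
        folds = [FoldSpec(fold=0, train=np.arange(6), test=np.arange(6, 9))]
        acc = decode_condition(X, labels, folds)
        assert acc == pytest.approx(2 / 3)

    def test_matches_manual_sklearn_cross_validation(self):
        # pooled CV accuracy equals an explicit per-fold sklearn evaluation
        from sklearn.svm import SVC

        rng = np.random.default_rng(6)
        labels = imbalanced_labels(8, 4, rng=6)
        X = rng.normal(size=(12, 5)) + np.where(labels == "B", 0.8, 0.0)[:, None]
        folds = make_running_index_folds(labels)
        correct = total = 0
        for f in folds:
            clf = SVC(kernel="linear", C=1.0).fit(X[f.train], labels[f.train])
            correct += (clf.predict(X[f.test]) == labels[f.test]).sum()
            total += len(f.test)
        assert decode_condition(X, labels, folds) == pytest.approx(correct / total)

    def test_engines_agree(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            X = rng.normal(size=(n, int(rng.integers(2, 12))))
            y = rng.integers(0, 2, size=n).astype(float)
            if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 1:
                continue
            Xt = rng.normal(size=(5, X.shape[1]))
            fast = _fit_decision(X, y, Xt, ClassifierSpec(engine="libsvm"))
            ref = _fit_decision(X, y, Xt, ClassifierSpec(engine="sklearn"))
            assert np.allclose(fast, ref, atol=1e-8)

    def test_random_labels_average_half_for_balanced_classes(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 6))
        accs = []
        for _ in range(150):
            labels = np.array(["a"] * 12 + ["b"] * 12)[rng.permutation(24)]
            accs.append(decode_condition(X, labels, make_running_index_folds(labels)))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_training_fold_rejected(self):
        X = np.zeros((6, 2))
        folds = [FoldSpec(fold=0, train=np.arange(3), test=np.arange(3, 6))]
        with pytest.raises(ValueError, match="single-class"):
            decode_condition(X, ["a", "a", "a", "b", "b", "b"], folds)


class TestSubsampleNs:
    def test_counts_mirror_cs_condition(self):
        labels = np.array(["NS1", "NS2"] * 24)
        keep = subsample_ns(labels, rng=0)
        assert len(keep) == 36
        counts = pd.Series(labels[keep]).value_counts()
        assert sorted(counts) == [12, 24]

    def test_either_stimulus_removed_equally_often(self):
        labels = np.array(["NS1", "NS2"] * 24)
        victims = []
        for seed in range(300):
            keep = subsample_ns(labels, rng=seed)
            counts = pd.Series(labels[keep]).value_counts()
            victims.append(counts.idxmin())
        frac = np.mean(np.array(victims) == "NS1")
        assert 0.4 < frac < 0.6

    def test_zero_removal_returns_all(self):
        labels = np.array(["NS1", "NS2"] * 5)
        assert list(subsample_ns(labels, rng=1, n_remove=0)) == list(range(10))

    def test_chronological_order_preserved(self):
        labels = np.array(["NS1", "NS2"] * 24)
        keep = subsample_ns(labels, rng=2)
        assert np.all(np.diff(keep) > 0)


class TestPermutationChance:
    def test_identical_seed_identical_null(self):
        rng = np.random.default_rng(9)
        labels = imbalanced_labels(rng=9)
        X = rng.normal(size=(36, 8))
        _, _, null_a = permutation_chance(X, labels, 25, rng=42)
        _, _, null_b = permutation_chance(X, labels, 25, rng=42)
        assert np.array_equal(null_a, null_b)

    def test_imbalanced_chance_exceeds_half(self):
        # with 2:1 training imbalance the classifier favours the majority
        # class, so the empirical chance is far from the naive 0.5
        rng = np.random.default_rng(10)
        labels = imbalanced_labels(rng=10)
        X = rng.normal(size=(36, 8))
        chance_mean, _, _ = permutation_chance(X, labels, 120, rng=0)
        assert chance_mean > 0.55

    def test_signal_exceeds_null_maximum(self):
        rng = np.random.default_rng(11)
        labels = imbalanced_labels(rng=11)
        X = np.where(labels == "A", -3.0, 3.0)[:, None] + rng.normal(size=(36, 4)) * 0.2
        folds = make_running_index_folds(labels)
        raw = decode_condition(X, labels, folds)
        _, _, null = permutation_chance(X, labels, 100, rng=1)
        assert raw > null.max()

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_chance(np.zeros((6, 2)), ["a"] * 3 + ["b"] * 3, 0)


class TestExcessAccuracy:
    def test_arithmetic(self):
        assert excess_accuracy(0.75, 0.60) == pytest.approx(0.15)
        assert excess_accuracy(0.6, 0.6) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            excess_accuracy(1.2, 0.5)


class TestCrossDecode:
    def _pattern_sets(self, shared, seed, noise=0.3, n=36, n_vox=20, amp=1.0):
        rng = np.random.default_rng(seed)
        w_a = amp * rng.normal(size=n_vox)
        w_b = w_a if shared else amp * rng.normal(size=n_vox)
        labels = np.array(["p", "q"] * (n // 2))
        Xa = np.where(labels == "q", 1.0, -1.0)[:, None] * w_a + noise * rng.normal(size=(n, n_vox))
        Xb = np.where(labels == "q", 1.0, -1.0)[:, None] * w_b + noise * rng.normal(size=(n, n_vox))
        return Xa, Xb, labels

    def test_shared_pattern_transfers(self):
        Xa, Xb, labels = self._pattern_sets(shared=True, seed=12)
        res = cross_decode(Xa, labels, Xb, labels, n_perm=60, rng=0)
        assert res.excess_accuracy > 0.3

    def test_independent_patterns_do_not_transfer(self):
        # the pattern amplitude is kept small against the noise so that the
        # chance alignment of two independent directions decodes only weakly
        vals = []
        for seed in range(20):
            Xa, Xb, labels = self._pattern_sets(
                shared=False, seed=100 + seed, noise=1.0, n_vox=100, amp=0.3
            )
            res = cross_decode(Xa, labels, Xb, labels, n_perm=25, rng=seed)
            vals.append(res.excess_accuracy)
        assert abs(np.mean(vals)) < 0.1

    def test_swapped_label_matching_flips_motor_effect(self):
        # patterns locked to the motor response transfer positively under
        # response-matched labels and negatively once the matching is swapped
        Xa, Xb, labels = self._pattern_sets(shared=True, seed=13, noise=0.1)
        swapped = np.where(labels == "p", "q", "p")
        pos = cross_decode(Xa, labels, Xb, labels, n_perm=40, rng=2)
        neg = cross_decode(Xa, labels, Xb, swapped, n_perm=40, rng=2)
        assert pos.excess_accuracy > 0.3
        assert neg.excess_accuracy < -0.3

    def test_single_class_training_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            cross_decode(X, ["p"] * 4, X, ["p", "q", "p", "q"], n_perm=1, rng=0)


@pytest.fixture(scope="module")
def betas(default_design):
    p = SynthParams(n_voxels=40, seed=21)
    basis = make_pattern_basis(p)
    return simulate_betas(default_design, basis, p, rng=22, participant="sub-01", hemisphere="left")


class TestDecodeParticipant:
    def test_result_table_structure(self, betas):
        df = decode_participant(betas, n_perm=20, n_subsample_reps=3, rng=0)
        assert len(df) == 4
        assert set(df.context) == {"reinforcement", "nonreinforcement"}
        assert np.allclose(df.excess_accuracy, df.raw_accuracy - df.chance_mean)
        assert df.raw_accuracy.between(0, 1).all()

    def test_deterministic_given_seed(self, betas):
        a = decode_participant(betas, n_perm=15, n_subsample_reps=2, rng=7)
        b = decode_participant(betas, n_perm=15, n_subsample_reps=2, rng=7)
        pd.testing.assert_frame_equal(a, b)

    def test_trial_info_required(self):
        from fearpattern.containers import TrialBetaMatrix

        with pytest.raises(ValueError, match="trial_info"):
            decode_participant(TrialBetaMatrix(data=np.zeros((10, 3))), n_perm=1, rng=0)
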