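"""SVM evaluation stage: balancing, CV metrics, AUC, hill-climb."""

import numpy as np
import pandas as pd
import pytest

from apneapsg import evaluation, registry, selection
from apneapsg.evaluation import (KernelConfig, cumulative_class_sets,
                                 default_grid, hill_climb, kfold_cv, metrics,
                                 roc_auc, train_svm, undersample)


def blobs(n=100, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 1, (n // 2, 2)), rng.normal(sep, 1, (n // 2, 2))])
    y = np.array(["N"] * (n // 2) + ["A"] * (n // 2))
    return x, y


class TestUndersample:
    def test_balances_majority_down(self, rng):
        y = np.array(["N"] * 100 + ["A"] * 20)
        idx = undersample(y, rng)
        vals, counts = np.unique(y[idx], return_counts=True)
        assert dict(zip(vals, counts)) == {"A": 20, "N": 20}

    def test_balanced_input_unchanged(self, rng):
        y = np.array(["N", "A"] * 10)
        assert len(undersample(y, rng)) == 20

    def test_seeded_determinism(self):
        y = np.array(["N"] * 50 + ["A"] * 10)
        a = undersample(y, np.random.default_rng(3))
        b = undersample(y, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestTrainSvm:
    def test_separable_blobs_perfectly_fit_by_linear_kernel(self):
        x, y = blobs()
        model = train_svm(x, y, KernelConfig("linear", 1.0))
        pred = model.decision_function(x) > 0
        assert np.array_equal(pred, y == "A")

    def test_xor_needs_nonlinear_kernel(self, rng):
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]])
        x = np.vstack([rng.normal(c, 0.5, (50, 2)) for c in centers])
        y = np.array(["A"] * 100 + ["N"] * 100)
        rbf = train_svm(x, y, KernelConfig("rbf", 1.0, sigma=1.0))
        lin = train_svm(x, y, KernelConfig("linear", 1.0))
        acc_rbf = np.mean((rbf.decision_function(x) > 0) == (y == "A"))
        acc_lin = np.mean((lin.decision_function(x) > 0) == (y == "A"))
        assert acc_rbf > 0.9
        # a hyperplane can at best isolate one XOR corner (3 of 4 blobs)
        assert acc_lin <= 0.8

    def test_duplicate_point_does_not_change_separable_solution(self):
        x, y = blobs(n=60)
        big_c = KernelConfig("linear", 1000.0)
        base = train_svm(x, y, big_c)
        x2 = np.vstack([x, x[:1]])
        y2 = np.append(y, y[0])
        dup = train_svm(x2, y2, big_c)
        np.testing.assert_allclose(dup.decision_function(x),
                                   base.decision_function(x), atol=1e-6)


class TestMetrics:
    def test_perfect_confusion(self):
        assert metrics(10, 10, 0, 0) == (100.0, 100.0, 100.0)

    def test_hand_computed(self):
        sens, spec, acc = metrics(9, 8, 2, 1)
        assert (sens, spec, acc) == (90.0, 80.0, 85.0)

    def test_scale_invariance(self):
        assert metrics(9, 8, 2, 1) == metrics(63, 56, 14, 7)


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["A", "A", "N", "N"])
        assert roc_auc(scores, labels) == 100.0

    def test_all_tied_scores(self):
        assert roc_auc(np.ones(10), np.array(["A", "N"] * 5)) == 50.0

    def test_matches_pairwise_count_oracle(self, rng):
        scores = rng.normal(size=50).round(1)  # rounding forces ties
        labels = np.where(rng.random(50) < 0.5, "A", "N")
        if len(set(labels)) < 2:
            labels[0] = "A"
            labels[1] = "N"
        s_a = scores[labels == "A"]
        s_n = scores[labels == "N"]
        wins = sum((a > b) + 0.5 * (a == b) for a in s_a for b in s_n)
        expected = 100.0 * wins / (len(s_a) * len(s_n))
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-9)


class TestKfoldCv:
    def test_separated_data_near_perfect(self):
        x, y = blobs(n=200)
        ev = kfold_cv(x, y, KernelConfig("linear", 1.0), k=10, seed=0)
        assert ev.mean_accuracy >= 99.0
        assert 0 <= ev.mean_auc <= 100

    def test_label_permutation_chance_level(self, rng):
        x, _ = blobs(n=2000, sep=6.0)
        y = np.where(rng.random(2000) < 0.5, "A", "N")
        ev = kfold_cv(x, y, KernelConfig("linear", 1.0), k=10, seed=1)
        assert ev.mean_accuracy == pytest.approx(50.0, abs=5.0)

    def test_seeded_reproducibility(self):
        x, y = blobs(n=120, sep=2.0)
        a = kfold_cv(x, y, KernelConfig("rbf", 1.0, sigma=5.0), k=5, seed=42)
        b = kfold_cv(x, y, KernelConfig("rbf", 1.0, sigma=5.0), k=5, seed=42)
        np.testing.assert_array_equal(a.fold_accuracy, b.fold_accuracy)
        np.testing.assert_array_equal(a.fold_auc, b.fold_auc)


def toy_selection(n_a=3, n_e=3):
    """Selection result with Class A signal features and Class E noise."""
    cols = list(registry.FEATURE_COLUMNS[: n_a + n_e])
    lam = {c: 5 for c in cols[:n_a]} | {c: 1 for c in cols[n_a:]}
    sr = selection.SelectionResult(lambda_=lam, nu_psg=5, selected=cols)
    return selection.assign_classes(sr), cols


class TestHillClimb:
    def test_signal_in_class_a_only_selects_class_a(self, rng):
        sr, cols = toy_selection()
        n = 600
        y = np.where(rng.random(n) < 0.4, "A", "N")
        data = {}
        for c in cols[:3]:
            data[c] = rng.normal(0, 1, n) + 3.0 * (y == "A")
        for c in cols[3:]:
            data[c] = rng.normal(0, 1, n)
        frame = pd.DataFrame(data)
        frame["label"] = y
        grid = default_grid()
        result = hill_climb(frame, sr, grid=grid, k=5, seed=0)
        # B-D are empty so A..ABCD share the same features and tie exactly;
        # the earlier-set tie-break keeps A, and ABCDE (adding noise) loses
        assert result.chosen_set == "A"
        assert result.table.shape[0] == 5 * len(grid)

    def test_single_class_partition_trivially_chosen(self, rng):
        sr, cols = toy_selection(n_a=2, n_e=0)
        n = 200
        y = np.where(rng.random(n) < 0.5, "A", "N")
        frame = pd.DataFrame({c: rng.normal(0, 1, n) + 2.0 * (y == "A") for c in cols})
        frame["label"] = y
        grid = [KernelConfig("linear", 1.0)]
        result = hill_climb(frame, sr, grid=grid, k=4, seed=0)
        assert result.chosen_set == "A"

    def test_output_table_shape(self, rng):
        sr, cols = toy_selection()
        n = 300
        y = np.where(rng.random(n) < 0.5, "A", "N")
        frame = pd.DataFrame({c: rng.normal(size=n) + (y == "A") for c in cols})
        frame["label"] = y
        grid = [KernelConfig("linear", r) for r in (0.2, 1.0)]
        result = hill_climb(frame, sr, grid=grid, k=4, seed=0)
        nonempty_sets = [s for s, members in cumulative_class_sets(sr).items() if members]
        assert result.table.shape[0] == len(nonempty_sets) * len(grid)

    def test_cumulative_sets_nest(self):
        sr, _ = toy_selection()
        sets = cumulative_class_sets(sr)
        assert set(sets) == {"A", "AB", "ABC", "ABCD", "ABCDE"}
        for a, b in zip(list(sets.values())[:-1], list(sets.values())[1:]):
            assert set(a) <= set(b)


class TestGrid:
    def test_default_grid_is_21_configs(self):
        grid = default_grid()
        assert len(grid) == 21
        kernels = [g.kernel for g in grid]
        assert kernels.count("rbf") == 9
        assert kernels.count("poly") == 9
        assert kernels.count("linear") == 3
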