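"""Splitting, confusion counting and the closed-set FAR/FRR/K metrics."""

import numpy as np
import pytest

from ecgid import (
    DatasetSplit,
    GAFDataset,
    ValidationError,
    confusion_matrix,
    identification_metrics,
    k_ratio,
    split_dataset,
)


def toy_dataset(per_class=10, n_classes=10, size=4, seed=0):
    rng = np.random.default_rng(seed)
    n = per_class * n_classes
    images = rng.uniform(-1, 1, size=(n, size, size))
    images = (images + images.transpose(0, 2, 1)) / 2  # symmetric, in [-1, 1]
    labels = np.repeat([f"S{i:02d}" for i in range(n_classes)], per_class)
    return GAFDataset(images, labels)


def brute_force_metrics(confusion):
    """Independent per-probe counting oracle for accuracy/FRR/FAR."""
    c = confusion.shape[0]
    probes = []  # (true, predicted) pairs
    for i in range(c):
        for j in range(c):
            probes.extend([(i, j)] * int(confusion[i, j]))
    total = len(probes)
    accuracy = sum(1 for t, p in probes if t == p) / total
    frr = sum(1 for t, p in probes if t != p) / total
    rates = []
    for i in range(c):
        impostors = [(t, p) for t, p in probes if t != i]
        rates.append(
            sum(1 for t, p in impostors if p == i) / len(impostors) if impostors else 0.0
        )
    far = float(np.mean(rates))
    return accuracy, frr, far


class TestSplit:
    def test_stratified_80_10_10(self):
        ds = toy_dataset(per_class=100)
        tr, va, te = split_dataset(ds, DatasetSplit(seed=4))
        for part, count in ((tr, 80), (va, 10), (te, 10)):
            assert len(part) == count * 10
            values, counts = np.unique(part.labels, return_counts=True)
            assert values.size == 10 and set(counts) == {count}

    def test_partition_is_exact(self):
        ds = toy_dataset(per_class=24)
        tr, va, te = split_dataset(ds, DatasetSplit(seed=1))
        assert len(tr) + len(va) + len(te) == len(ds)

    def test_deterministic_given_seed(self):
        ds = toy_dataset(per_class=24)
        a = split_dataset(ds, DatasetSplit(seed=9))
        b = split_dataset(ds, DatasetSplit(seed=9))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.images, pb.images)

    def test_too_small_class_rejected(self):
        ds = toy_dataset(per_class=2)
        with pytest.raises(ValidationError):
            split_dataset(ds, DatasetSplit())

    def test_two_way_split_with_zero_val(self):
        ds = toy_dataset(per_class=10)
        tr, va, te = split_dataset(ds, DatasetSplit(train=0.8, val=0.0, test=0.2))
        assert len(va) == 0
        assert len(tr) == 80 and len(te) == 20

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            DatasetSplit(train=0.8, val=0.1, test=0.2)


class TestConfusion:
    def test_perfect_predictions(self):
        y = np.repeat(["a", "b", "c"], 5)
        m = confusion_matrix(y, y, np.array(["a", "b", "c"]))
        np.testing.assert_array_equal(m, 5 * np.eye(3, dtype=int))

    def test_total_confusion_binary(self):
        true = np.array(["A"] * 5 + ["B"] * 5)
        pred = np.array(["B"] * 10)
        m = confusion_matrix(true, pred, np.array(["A", "B"]))
        np.testing.assert_array_equal(m, [[0, 5], [0, 5]])

    def test_count_conservation(self, rng):
        classes = np.array(["x", "y", "z"])
        true = rng.choice(classes, 71)
        pred = rng.choice(classes, 71)
        assert confusion_matrix(true, pred, classes).sum() == 71

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion_matrix(np.array(["a"]), np.array(["q"]), np.array(["a", "b"]))


class TestIdentificationMetrics:
    def test_balanced_ten_class_closed_form(self):
        """27 misclassifications per class, uniform: FRR=0.09, FAR=0.01, K=9."""
        c, per_class, errors = 10, 300, 27
        m = np.full((c, c), errors // (c - 1), dtype=int)
        np.fill_diagonal(m, per_class - errors)
        report = identification_metrics(m)
        assert report.frr == pytest.approx(0.09)
        assert report.far == pytest.approx(0.01)
        assert report.k == pytest.approx(9.0)

    def test_perfect_diagonal_has_undefined_k(self):
        report = identification_metrics(np.diag([7, 7, 7]))
        assert report.frr == 0.0 and report.far == 0.0
        assert report.k is None

    def test_reported_error_rates_give_k_nine(self):
        # closed-set identification errors reported as FAR=0.01022, FRR=0.09254
        assert round(k_ratio(0.09254, 0.01022)) == 9

    def test_balanced_k_equals_classes_minus_one(self, rng):
        """With balanced probe counts and any error pattern, K == C-1 exactly."""
        for _ in range(50):
            c = int(rng.integers(2, 12))
            per_class = int(rng.integers(20, 60))
            m = rng.multinomial(per_class, np.ones(c) / c, size=c)
            if np.trace(m) == per_class * c:
                continue  # K undefined for perfect matrices
            report = identification_metrics(m)
            assert report.k == pytest.approx(c - 1)
            bf_acc, bf_frr, bf_far = brute_force_metrics(m)
            assert report.far == pytest.approx(bf_far)

    def test_agrees_with_counting_oracle_on_random_vectors(self, rng):
        classes = np.arange(6).astype(str)
        for _ in range(200):
            n = int(rng.integers(10, 80))
            true = rng.choice(classes, n)
            pred = rng.choice(classes, n)
            m = confusion_matrix(true, pred, classes)
            report = identification_metrics(m)
            bf_acc, bf_frr, bf_far = brute_force_metrics(m)
            assert report.accuracy == pytest.approx(bf_acc)
            assert report.frr == pytest.approx(bf_frr)
            assert report.far == pytest.approx(bf_far)

    def test_threshold_monotonicity(self, rng):
        """Raising tau never lowers FRR and never raises FAR."""
        n, c = 200, 5
        probs = rng.dirichlet(np.ones(c) * 0.5, size=n)
        true = rng.integers(0, c, n)
        conf = np.zeros((c, c), dtype=int)
        np.add.at(conf, (true, probs.argmax(axis=1)), 1)
        prev_frr, prev_far = -1.0, 2.0
        for tau in np.linspace(0.0, 1.0, 11):
            rep = identification_metrics(conf, tau=tau, probabilities=probs, true_indices=true)
            assert rep.frr >= prev_frr - 1e-12
            assert rep.far <= prev_far + 1e-12
            prev_frr, prev_far = rep.frr, rep.far

    def test_reject_everything_threshold(self, rng):
        c = 4
        probs = rng.dirichlet(np.ones(c), size=40)
        true = rng.integers(0, c, 40)
        conf = np.zeros((c, c), dtype=int)
        np.add.at(conf, (true, probs.argmax(axis=1)), 1)
        rep = identification_metrics(conf, tau=1.01, probabilities=probs, true_indices=true)
        assert rep.frr == 1.0 and rep.far == 0.0

    def test_accuracy_plus_frr_is_one_without_threshold(self, rng):
        m = rng.integers(0, 30, size=(4, 4))
        m = np.asarray(m, dtype=int)
        m[0, 0] += 1  # ensure non-empty
        rep = identification_metrics(m)
        assert rep.accuracy + rep.frr == pytest.approx(1.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            identification_metrics(np.ones((2, 3), dtype=int))
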