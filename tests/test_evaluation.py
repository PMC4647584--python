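"""Cross-validation engines and metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gridrun as g
from gridrun.evaluation import EvaluationError, fold_assignment

from conftest import random_dataset


def labelled_dataset(labels, levels=("A", "B", "C")):
    labels = np.asarray(labels, dtype=np.int64)
    return g.Dataset(
        "t",
        [g.AttributeSchema("x", "numeric"),
         g.AttributeSchema("cls", "nominal", tuple(levels))],
        [np.arange(len(labels), dtype=float), labels],
    )


def zeror_loocv_closed_form(counts):
    """Accuracy of LOOCV ZeroR from class counts alone.

    Holding out one instance of class c leaves counts with n_c - 1; the
    prediction is the modal class of the remainder (ties to the lowest
    code).  Independent enumeration, no learner involved.
    """
    counts = np.asarray(counts)
    n = counts.sum()
    correct = 0
    for c, n_c in enumerate(counts):
        if n_c == 0:
            continue
        rest = counts.copy()
        rest[c] -= 1
        if int(np.argmax(rest)) == c:
            correct += n_c
    return correct / n


class TestLoocv:
    def test_zeror_three_one(self):
        ds = labelled_dataset([0, 0, 0, 1])
        reg = g.default_registry()
        res = g.loocv(ds, lambda: reg.build("zeror", {}))
        assert res.metrics.accuracy == pytest.approx(0.75)
        assert res.n_instances == 4

    def test_duplicated_points_are_perfect_for_1nn(self):
        ds = g.Dataset(
            "t",
            [g.AttributeSchema("x", "numeric"),
             g.AttributeSchema("cls", "nominal", ("A", "B"))],
            [np.array([0.0, 0.0, 5.0, 5.0]), np.array([0, 0, 1, 1])],
        )
        reg = g.default_registry()
        res = g.loocv(ds, lambda: reg.build("knn", {"k": 1}))
        assert res.metrics.accuracy == 1.0

    def test_single_row_is_an_error(self):
        ds = labelled_dataset([0])
        with pytest.raises(EvaluationError):
            g.loocv(ds, lambda: g.default_registry().build("zeror", {}))

    def test_fold_lacking_a_class_still_scored(self):
        # the sole B instance is scored against a training set of pure A
        ds = labelled_dataset([0, 0, 1])
        reg = g.default_registry()
        res = g.loocv(ds, lambda: reg.build("zeror", {}))
        assert res.confusion.sum() == 3
        assert res.confusion[1, 0] == 1  # the B row, predicted A

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40)
    def test_zeror_accuracy_matches_closed_form(self, seed):
        """LOOCV of the majority baseline equals the class-count formula."""
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng)
        labelled = ds.y[ds.y >= 0]
        if len(labelled) < 2:
            return
        counts = np.bincount(labelled, minlength=len(ds.class_levels))
        reg = g.default_registry()
        res = g.loocv(ds, lambda: reg.build("zeror", {}))
        assert res.metrics.accuracy == pytest.approx(zeror_loocv_closed_form(counts))


class TestFoldAssignment:
    def test_sizes_differ_by_at_most_one(self):
        folds = fold_assignment(np.zeros(10, dtype=int), 3, seed=0, stratified=False)
        sizes = sorted(np.bincount(folds, minlength=3), reverse=True)
        assert sizes == [4, 3, 3]

    def test_stratified_round_robin_dealing(self):
        labels = np.array([0] * 6 + [1] * 4)
        folds = fold_assignment(labels, 2, seed=5, stratified=True)
        for f in range(2):
            assert (labels[folds == f] == 0).sum() == 3
            assert (labels[folds == f] == 1).sum() == 2

    def test_stratified_overall_balance_across_classes(self):
        # three classes of 3: the dealing pointer must carry across classes
        labels = np.repeat([0, 1, 2], 3)
        folds = fold_assignment(labels, 2, seed=1, stratified=True)
        sizes = np.bincount(folds, minlength=2)
        assert abs(sizes[0] - sizes[1]) <= 1

    def test_pure_function_of_inputs(self):
        labels = np.array([0, 1, 0, 1, 0, 1, 1, 0])
        a = fold_assignment(labels, 3, seed=9, stratified=True)
        b = fold_assignment(labels, 3, seed=9, stratified=True)
        assert np.array_equal(a, b)
        c = fold_assignment(labels, 3, seed=10, stratified=True)
        assert not np.array_equal(a, c)

    def test_k_out_of_range(self):
        with pytest.raises(EvaluationError):
            fold_assignment(np.zeros(4, dtype=int), 5, 0, False)
        with pytest.raises(EvaluationError):
            fold_assignment(np.zeros(4, dtype=int), 1, 0, False)


class TestKfold:
    @pytest.mark.parametrize("learner,params", [
        ("zeror", {}), ("knn", {"k": 1}), ("stump", {"min_leaf": 1}),
    ])
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=10)
    def test_k_equals_n_is_loocv(self, learner, params, seed):
        """k = n (unstratified) pools to exactly the LOOCV result."""
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng)
        n = int((ds.y >= 0).sum())
        if n < 2:
            return
        reg = g.default_registry()
        builder = lambda: reg.build(learner, params)
        a = g.loocv(ds, builder)
        b = g.kfold(ds, builder, k=n, seed=seed % 1000, stratified=False)
        assert np.array_equal(a.confusion, b.confusion)
        assert a.metrics == b.metrics

    def test_confusion_total_is_n(self, small_dataset):
        reg = g.default_registry()
        res = g.kfold(small_dataset, lambda: reg.build("stump", {}), k=5, seed=0)
        assert res.confusion.sum() == (small_dataset.y >= 0).sum()


class TestPercentageSplit:
    def test_floor_rule(self):
        ds = labelled_dataset(np.arange(100) % 2, levels=("A", "B"))
        reg = g.default_registry()
        res = g.percentage_split(ds, lambda: reg.build("zeror", {}), 0.66, seed=0)
        assert res.n_instances == 34  # test fold = 100 - floor(66)

    def test_deterministic_under_seed(self, small_dataset):
        reg = g.default_registry()
        builder = lambda: reg.build("knn", {"k": 3})
        a = g.percentage_split(small_dataset, builder, 0.7, seed=4)
        b = g.percentage_split(small_dataset, builder, 0.7, seed=4)
        assert np.array_equal(a.confusion, b.confusion)

    @pytest.mark.parametrize("fraction", [1.0, 0.0, 0.001])
    def test_empty_partition_is_an_error(self, fraction):
        ds = labelled_dataset([0, 1, 0, 1])
        with pytest.raises(EvaluationError):
            g.percentage_split(ds, lambda: g.default_registry().build("zeror", {}),
                               fraction, seed=0)


def bruteforce_metrics(conf):
    """Direct per-class formula evaluation, plain Python."""
    conf = np.asarray(conf, dtype=float)
    c = conf.shape[0]
    total = conf.sum()
    acc = sum(conf[i, i] for i in range(c)) / total
    precision, recall, f1 = [], [], []
    for i in range(c):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    p_e = sum(conf[i, :].sum() * conf[:, i].sum() for i in range(c)) / total**2
    kappa = 0.0 if p_e == 1 else (acc - p_e) / (1 - p_e)
    return acc, precision, recall, f1, kappa


class TestMetrics:
    def test_hand_checked_two_class_matrix(self):
        m = g.compute_metrics([[3, 1], [2, 4]])
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision[0] == pytest.approx(0.6)
        assert m.recall[0] == pytest.approx(0.75)
        assert m.kappa == pytest.approx(0.4)

    def test_perfect_diagonal(self):
        m = g.compute_metrics(np.diag([5, 3, 2]))
        assert m.accuracy == 1.0
        assert m.kappa == 1.0
        assert all(p == 1.0 for p in m.precision + m.recall + m.f1)

    def test_single_class_kappa_convention(self):
        m = g.compute_metrics([[7]])
        assert m.kappa == 0.0
        assert m.accuracy == 1.0

    def test_never_predicted_class_zero_denominators(self):
        m = g.compute_metrics([[2, 0], [3, 0]])
        assert m.precision[1] == 0.0
        assert m.recall[1] == 0.0
        assert m.f1[1] == 0.0

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(EvaluationError):
            g.compute_metrics([[0, 0], [0, 0]])

    @given(st.integers(1, 5), st.integers(0, 2**31 - 1))
    @settings(max_examples=50)
    def test_matches_bruteforce_and_sklearn(self, c, seed):
        """compute_metrics agrees with direct formulas and with sklearn."""
        rng = np.random.default_rng(seed)
        conf = rng.integers(0, 10, size=(c, c))
        if conf.sum() == 0:
            conf[0, 0] = 1
        m = g.compute_metrics(conf)
        acc, precision, recall, f1, kappa = bruteforce_metrics(conf)
        assert m.accuracy == pytest.approx(acc)
        assert m.kappa == pytest.approx(kappa)
        assert np.allclose(m.precision, precision)
        assert np.allclose(m.recall, recall)
        assert np.allclose(m.f1, f1)

        from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

        y_true = np.concatenate(
            [np.full(conf[i, j], i) for i in range(c) for j in range(c)]
        )
        y_pred = np.concatenate(
            [np.full(conf[i, j], j) for i in range(c) for j in range(c)]
        )
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=np.arange(c), zero_division=0
        )
        assert np.allclose(m.precision, p)
        assert np.allclose(m.recall, r)
        assert np.allclose(m.f1, f)
        if len(np.unique(np.concatenate([y_true, y_pred]))) > 1:
            assert m.kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred, labels=np.arange(c))
            )
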