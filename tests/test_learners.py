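"""Reference learners: majority baseline, k-NN, decision stump, registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gridrun as g
from gridrun.learners import (
    DecisionStump,
    KNearestNeighbours,
    LearnerError,
    ZeroR,
)

from conftest import random_dataset


def numeric_dataset(x_values, labels, levels=("A", "B")):
    """One numeric attribute plus a nominal class."""
    return g.Dataset(
        "t",
        [g.AttributeSchema("x", "numeric"),
         g.AttributeSchema("cls", "nominal", tuple(levels))],
        [np.asarray(x_values, dtype=float), np.asarray(labels, dtype=np.int64)],
    )


class TestZeroR:
    def test_predicts_majority(self):
        ds = numeric_dataset([0, 1, 2], [0, 0, 1])
        model = ZeroR().fit(ds, np.arange(3))
        assert model.predict(ds, np.arange(3)).tolist() == [0, 0, 0]

    def test_tie_goes_to_first_declared_level(self):
        ds = numeric_dataset([0, 1], [0, 1])
        model = ZeroR().fit(ds, np.arange(2))
        assert model.predict(ds, [0]).tolist() == [0]

    def test_empty_training_set_is_an_error(self):
        ds = numeric_dataset([0.0], [0])
        with pytest.raises(LearnerError):
            ZeroR().fit(ds, np.array([], dtype=int))


class TestKNN:
    def test_one_nn_hand_example(self):
        # train x=0 -> A, x=10 -> B; query x=1 is nearer 0
        ds = numeric_dataset([0, 10, 1], [0, 1, -1])
        model = KNearestNeighbours(k=1).fit(ds, np.array([0, 1]))
        assert model.predict(ds, [2]).tolist() == [0]

    def test_query_equal_to_training_point(self):
        ds = numeric_dataset([0, 10, 10], [0, 1, -1])
        model = KNearestNeighbours(k=1).fit(ds, np.array([0, 1]))
        assert model.predict(ds, [2]).tolist() == [1]

    def test_three_nn_majority_vote(self):
        ds = numeric_dataset([0, 1, 10, 0.5], [0, 0, 1, -1])
        model = KNearestNeighbours(k=3).fit(ds, np.array([0, 1, 2]))
        assert model.predict(ds, [3]).tolist() == [0]

    def test_nominal_and_missing_distance_contributions(self):
        # two nominal attributes; query matches train row 0 on both,
        # mismatches row 1 on both -> row 0 wins
        ds = g.Dataset(
            "t",
            [g.AttributeSchema("u", "nominal", ("p", "q")),
             g.AttributeSchema("v", "nominal", ("p", "q")),
             g.AttributeSchema("cls", "nominal", ("A", "B"))],
            [np.array([0, 1, 0]), np.array([0, 1, 0]), np.array([0, 1, -1])],
        )
        model = KNearestNeighbours(k=1).fit(ds, np.array([0, 1]))
        assert model.predict(ds, [2]).tolist() == [0]

    def test_distance_tie_broken_by_training_row_index(self):
        ds = numeric_dataset([-1, 1, 0], [1, 0, -1])  # both at distance 1
        model = KNearestNeighbours(k=1).fit(ds, np.array([0, 1]))
        assert model.predict(ds, [2]).tolist() == [1]  # row 0 (label B) wins

    def test_k_exceeding_training_size(self):
        ds = numeric_dataset([0, 1], [0, 1])
        with pytest.raises(LearnerError):
            KNearestNeighbours(k=3).fit(ds, np.arange(2))

    def test_constant_attribute_ignored(self):
        ds = g.Dataset(
            "t",
            [g.AttributeSchema("flat", "numeric"),
             g.AttributeSchema("x", "numeric"),
             g.AttributeSchema("cls", "nominal", ("A", "B"))],
            [np.array([5.0, 5.0, 5.0]), np.array([0.0, 10.0, 1.0]),
             np.array([0, 1, -1])],
        )
        model = KNearestNeighbours(k=1).fit(ds, np.array([0, 1]))
        assert model.predict(ds, [2]).tolist() == [0]


# --------------------------------------------------------------------------
# decision stump vs exhaustive oracle


def _oracle_entropy(counts):
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum(
        (c / total) * math.log2(c / total) for c in counts if c > 0
    )


def oracle_best_gain(dataset, rows, min_leaf):
    """Exhaustive search over every (attribute, binary split) pair.

    Independent of the implementation: plain Python loops, direct
    counting, same missing-value routing (missing -> 'no' branch).
    """
    rows = [r for r in rows if dataset.y[r] >= 0]
    y = [int(dataset.y[r]) for r in rows]
    c = len(dataset.class_levels)
    n = len(rows)
    base = _oracle_entropy([y.count(k) for k in range(c)])
    best = -1.0
    for j, attr in enumerate(dataset.attributes):
        if j == dataset.class_index:
            continue
        col = [dataset.columns[j][r] for r in rows]
        if attr.kind == "numeric":
            vals = sorted({v for v in col if not np.isnan(v)})
            cuts = [(a + b) / 2 for a, b in zip(vals, vals[1:])]
            tests = [lambda v, t=t: (not np.isnan(v)) and v <= t for t in cuts]
        else:
            tests = [lambda v, lv=lv: v == lv for lv in range(len(attr.levels))]
        for test in tests:
            yes = [k for k in range(n) if test(col[k])]
            no = [k for k in range(n) if not test(col[k])]
            if len(yes) < min_leaf or len(no) < min_leaf:
                continue
            gain = base - (
                len(yes) / n * _oracle_entropy([sum(1 for k in yes if y[k] == cc) for cc in range(c)])
                + len(no) / n * _oracle_entropy([sum(1 for k in no if y[k] == cc) for cc in range(c)])
            )
            best = max(best, gain)
    return best


class TestDecisionStump:
    def test_perfect_separator_found(self):
        ds = numeric_dataset([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        model = DecisionStump(min_leaf=1).fit(ds, np.arange(6))
        assert model.predict(ds, np.arange(6)).tolist() == [0, 0, 0, 1, 1, 1]
        assert model._rule[2] == pytest.approx(6.5)

    def test_constant_labels_degenerate_stump(self):
        ds = numeric_dataset([1, 2, 3], [0, 0, 0])
        model = DecisionStump().fit(ds, np.arange(3))
        assert model._rule is None
        assert model.predict(ds, np.arange(3)).tolist() == [0, 0, 0]

    def test_informative_attribute_beats_noise(self):
        ds = g.Dataset(
            "t",
            [g.AttributeSchema("noise", "numeric"),
             g.AttributeSchema("signal", "numeric"),
             g.AttributeSchema("cls", "nominal", ("A", "B"))],
            [np.array([1.0, 2.0, 1.0, 2.0]),
             np.array([0.0, 0.0, 5.0, 5.0]),
             np.array([0, 0, 1, 1])],
        )
        model = DecisionStump().fit(ds, np.arange(4))
        assert model._rule[0] == 1  # the signal attribute

    def test_min_leaf_forces_degenerate_stump(self):
        ds = numeric_dataset([1, 2, 3, 4], [0, 0, 0, 1])
        model = DecisionStump(min_leaf=3).fit(ds, np.arange(4))
        assert model._rule is None
        assert model.predict(ds, [0]).tolist() == [0]

    def test_missing_values_routed_to_else_branch(self):
        ds = numeric_dataset([1, 2, 10, 11, np.nan], [0, 0, 1, 1, -1])
        model = DecisionStump().fit(ds, np.arange(5))
        assert model.predict(ds, [4]).tolist() == [1]

    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    @settings(max_examples=30)
    def test_matches_exhaustive_oracle(self, seed, min_leaf):
        """Chosen split achieves the exhaustively-verified maximum gain."""
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_rows=int(rng.integers(6, 30)))
        rows = np.arange(ds.n_rows)
        model = DecisionStump(min_leaf=min_leaf).fit(ds, rows)
        best = oracle_best_gain(ds, rows, min_leaf)
        if model._rule is None:
            assert best <= 1e-12  # no admissible or useful split existed
        else:
            labelled = rows[ds.y[rows] >= 0]
            y = ds.y[labelled]
            c = len(ds.class_levels)
            base = _oracle_entropy(np.bincount(y, minlength=c).tolist())
            attr_idx, kind, cut, yes_pred, no_pred = model._rule
            col = ds.columns[attr_idx][labelled]
            if kind == "numeric":
                with np.errstate(invalid="ignore"):
                    yes = (~np.isnan(col)) & (col <= cut)
            else:
                yes = col == cut
            gain = base - (
                yes.sum() / len(y) * _oracle_entropy(np.bincount(y[yes], minlength=c).tolist())
                + (~yes).sum() / len(y) * _oracle_entropy(np.bincount(y[~yes], minlength=c).tolist())
            )
            assert gain == pytest.approx(best, abs=1e-9)


class TestRegistry:
    def test_builtin_construction(self):
        reg = g.default_registry()
        assert isinstance(reg.build("zeror", {}), ZeroR)
        knn = reg.build("knn", {"k": 3})
        assert isinstance(knn, KNearestNeighbours) and knn.k == 3

    def test_unknown_parameter_named_in_error(self):
        reg = g.default_registry()
        with pytest.raises(LearnerError, match="'c'"):
            reg.build("knn", {"c": 0.25})

    def test_unknown_key_lists_registered(self):
        reg = g.default_registry()
        with pytest.raises(LearnerError, match="knn"):
            reg.build("j48", {})

    def test_duplicate_key_rejected(self):
        reg = g.default_registry()
        with pytest.raises(LearnerError):
            reg.register("knn", lambda p, s: None, ())

    def test_sklearn_adapter_end_to_end(self):
        """A C4.5-style sklearn tree plugs in through the adapter contract."""
        from sklearn.tree import DecisionTreeClassifier

        reg = g.default_registry()
        reg.register_sklearn("cart", DecisionTreeClassifier, ("max_depth",))
        ds = g.make_synthetic(60, n_numeric=4, n_classes=2, class_sep=4.0, seed=2)
        res = g.kfold(ds, lambda: reg.build("cart", {"max_depth": 3}, seed=0), k=5)
        assert res.metrics.accuracy > 0.8
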