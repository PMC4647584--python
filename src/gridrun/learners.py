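"""Built-in reference classifiers and the learner registry.

The evaluation engine only needs a narrow contract: ``fit(dataset, rows)``
followed by ``predict(dataset, rows)`` returning class codes drawn from
the dataset's declared class levels.  Three dependency-free learners
implement it:

``zeror``
    Majority-class baseline (ties go to the first-declared level).
``knn``
    k-nearest neighbours with Euclidean distance on standardised numeric
    attributes; a nominal attribute contributes 0 if equal and 1 if
    different; a missing cell (on either side) contributes 1 to the
    squared distance.  Distance ties are broken by lower training-row
    index, vote ties by first-declared level.
``stump``
    One-level decision tree maximising information gain over all single
    binary splits (numeric thresholds at midpoints of consecutive
    distinct values; nominal one-vs-rest on a level), subject to both
    leaves holding at least ``min_leaf`` training rows.  ``min_leaf`` is
    the tunable regularisation knob that gives a grid search something
    real to optimise.  Rows whose split attribute is missing follow the
    "else" branch.  Gain ties prefer the lowest attribute index, then
    the lowest threshold (or level code).

All three are deterministic given the training data and hyper-parameters.
External estimators with an sklearn-style ``fit(X, y)``/``predict(X)``
surface can be registered through :class:`SklearnAdapter`.
"""

from __future__ import annotations

import math
from decimal import Decimal

import numpy as np

__all__ = [
    "LearnerError",
    "ZeroR",
    "KNearestNeighbours",
    "DecisionStump",
    "SklearnAdapter",
    "LearnerRegistry",
    "default_registry",
]


class LearnerError(Exception):
    pass


def _coerce_number(v):
    if isinstance(v, Decimal):
        return int(v) if v == v.to_integral_value() else float(v)
    return v


def _majority(labels: np.ndarray, n_classes: int) -> int:
    """Modal class code; ties resolved to the lowest code (first level)."""
    labels = labels[labels >= 0]
    if len(labels) == 0:
        raise LearnerError("no labelled training rows")
    return int(np.argmax(np.bincount(labels, minlength=n_classes)))


class ZeroR:
    """Predict the modal training class for every query."""

    key = "zeror"

    def __init__(self):
        self._modal = None

    def fit(self, dataset, rows):
        rows = np.asarray(rows, dtype=np.intp)
        if len(rows) == 0:
            raise LearnerError("cannot fit on an empty training set")
        self._modal = _majority(dataset.y[rows], len(dataset.class_levels))
        return self

    def predict(self, dataset, rows):
        if self._modal is None:
            raise LearnerError("fit must precede predict")
        return np.full(len(rows), self._modal, dtype=np.int64)


class KNearestNeighbours:
    key = "knn"

    def __init__(self, k: int = 1):
        k = _coerce_number(k)
        if not isinstance(k, int) or k < 1:
            raise LearnerError(f"k must be a positive integer, got {k!r}")
        self.k = k
        self._fitted = None

    def fit(self, dataset, rows):
        rows = np.asarray(rows, dtype=np.intp)
        if self.k > len(rows):
            raise LearnerError(
                f"k={self.k} exceeds training size {len(rows)}"
            )
        x_num, x_nom, _, _ = dataset.features()
        tn = x_num[rows]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(tn, axis=0) if tn.shape[1] else np.empty(0)
            sd = np.nanstd(tn, axis=0) if tn.shape[1] else np.empty(0)
        mean = np.nan_to_num(mean)  # all-missing column: sd 0, ignored anyway
        active = sd > 0
        z_train = (tn[:, active] - mean[active]) / sd[active]
        self._fitted = {
            "mean": mean,
            "sd": sd,
            "active": active,
            "z_train": z_train,
            "nom_train": x_nom[rows],
            "y_train": dataset.y[rows],
            "n_classes": len(dataset.class_levels),
        }
        return self

    def predict(self, dataset, rows):
        if self._fitted is None:
            raise LearnerError("fit must precede predict")
        f = self._fitted
        rows = np.asarray(rows, dtype=np.intp)
        x_num, x_nom, _, _ = dataset.features()
        qn = x_num[rows][:, f["active"]]
        z_query = (qn - f["mean"][f["active"]]) / f["sd"][f["active"]]
        z_train = f["z_train"]

        # squared numeric contribution; any missing cell contributes 1
        diff = z_query[:, None, :] - z_train[None, :, :]
        sq = diff * diff
        sq = np.where(np.isnan(sq), 1.0, sq)
        d2 = sq.sum(axis=2)

        nq = x_nom[rows]
        nt = f["nom_train"]
        if nq.shape[1]:
            mismatch = (nq[:, None, :] != nt[None, :, :]) | (
                nq[:, None, :] < 0
            ) | (nt[None, :, :] < 0)
            d2 = d2 + mismatch.sum(axis=2)

        preds = np.empty(len(rows), dtype=np.int64)
        for i in range(len(rows)):
            order = np.argsort(d2[i], kind="stable")[: self.k]
            votes = f["y_train"][order]
            preds[i] = _majority(votes, f["n_classes"])
        return preds


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


class DecisionStump:
    key = "stump"

    def __init__(self, min_leaf: int = 1):
        min_leaf = _coerce_number(min_leaf)
        if not isinstance(min_leaf, int) or min_leaf < 1:
            raise LearnerError(
                f"min_leaf must be a positive integer, got {min_leaf!r}"
            )
        self.min_leaf = min_leaf
        self._rule = None  # (attr_index, kind, threshold_or_level, yes_pred, no_pred)
        self._default = None

    def fit(self, dataset, rows):
        rows = np.asarray(rows, dtype=np.intp)
        y_all = dataset.y[rows]
        labelled = rows[y_all >= 0]
        y = dataset.y[labelled]
        if len(labelled) == 0:
            raise LearnerError("no labelled training rows")
        c = len(dataset.class_levels)
        total_counts = np.bincount(y, minlength=c)
        self._default = int(np.argmax(total_counts))
        self._rule = None
        if (total_counts > 0).sum() < 2:
            return self  # constant labels: degenerate majority stump

        base = _entropy(total_counts)
        n = len(labelled)
        best_gain = -1.0

        for attr_idx, attr in enumerate(dataset.attributes):
            if attr_idx == dataset.class_index:
                continue
            col = dataset.columns[attr_idx][labelled]
            if attr.kind == "numeric":
                found = self._best_numeric(col, y, c, total_counts, base, n)
            else:
                found = self._best_nominal(col, y, c, total_counts, base, n, attr)
            if found is not None and found[0] > best_gain + 1e-12:
                best_gain = found[0]
                self._rule = (attr_idx,) + found[1:]
        return self

    def _leaf_preds(self, yes_counts, no_counts):
        return int(np.argmax(yes_counts)), int(np.argmax(no_counts))

    def _best_numeric(self, col, y, c, total_counts, base, n):
        mask = ~np.isnan(col)
        if mask.sum() < 2:
            return None
        v = col[mask]
        lab = y[mask]
        order = np.argsort(v, kind="stable")
        v_sorted = v[order]
        lab_sorted = lab[order]
        onehot = np.zeros((len(v), c))
        onehot[np.arange(len(v)), lab_sorted] = 1.0
        cum = np.cumsum(onehot, axis=0)  # cum[i] = class counts among first i+1
        boundary = np.nonzero(v_sorted[:-1] < v_sorted[1:])[0]
        if len(boundary) == 0:
            return None
        left_counts = cum[boundary]  # candidates x classes
        right_counts = total_counts[None, :] - left_counts
        left_sizes = boundary + 1
        right_sizes = n - left_sizes  # missing-value rows fall right
        ok = (left_sizes >= self.min_leaf) & (right_sizes >= self.min_leaf)
        if not ok.any():
            return None
        gains = np.full(len(boundary), -np.inf)
        for i in np.nonzero(ok)[0]:
            gains[i] = base - (
                left_sizes[i] / n * _entropy(left_counts[i])
                + right_sizes[i] / n * _entropy(right_counts[i])
            )
        best = int(np.argmax(gains))  # first max = lowest threshold
        threshold = float((v_sorted[boundary[best]] + v_sorted[boundary[best] + 1]) / 2)
        yes_pred, no_pred = self._leaf_preds(
            left_counts[best], right_counts[best]
        )
        return gains[best], "numeric", threshold, yes_pred, no_pred

    def _best_nominal(self, col, y, c, total_counts, base, n, attr):
        best = None
        for level in range(len(attr.levels)):  # lowest level code wins ties
            yes = col == level
            yes_n = int(yes.sum())
            no_n = n - yes_n  # missing codes (-1) fall on the "no" side
            if yes_n < self.min_leaf or no_n < self.min_leaf:
                continue
            yes_counts = np.bincount(y[yes], minlength=c)
            no_counts = total_counts - yes_counts
            gain = base - (
                yes_n / n * _entropy(yes_counts)
                + no_n / n * _entropy(no_counts)
            )
            if best is None or gain > best[0] + 1e-12:
                yes_pred, no_pred = self._leaf_preds(yes_counts, no_counts)
                best = (gain, "nominal", level, yes_pred, no_pred)
        return best

    def predict(self, dataset, rows):
        if self._default is None:
            raise LearnerError("fit must precede predict")
        rows = np.asarray(rows, dtype=np.intp)
        if self._rule is None:
            return np.full(len(rows), self._default, dtype=np.int64)
        attr_idx, kind, cut, yes_pred, no_pred = self._rule
        col = dataset.columns[attr_idx][rows]
        if kind == "numeric":
            with np.errstate(invalid="ignore"):
                yes = col <= cut  # NaN compares False: missing goes "no"
        else:
            yes = col == cut
        return np.where(yes, yes_pred, no_pred).astype(np.int64)


class SklearnAdapter:
    """Wrap an sklearn-style estimator behind the learner contract.

    Features are presented as a dense matrix: numeric columns as-is
    (missing = NaN) and nominal level codes as floats (missing = NaN).  The estimator must cope with whatever missingness
    the dataset carries.  ``seed`` is forwarded as ``random_state`` when
    the estimator accepts it.
    """

    def __init__(self, estimator_factory, params, seed=None):
        kwargs = {k: _coerce_number(v) for k, v in params.items()}
        if seed is not None:
            try:
                self._est = estimator_factory(random_state=seed, **kwargs)
            except TypeError:
                self._est = estimator_factory(**kwargs)
        else:
            self._est = estimator_factory(**kwargs)

    @staticmethod
    def _matrix(dataset, rows):
        x_num, x_nom, _, _ = dataset.features()
        nom = x_nom[rows].astype(np.float64)
        nom[nom < 0] = np.nan
        return np.hstack([x_num[rows], nom])

    def fit(self, dataset, rows):
        rows = np.asarray(rows, dtype=np.intp)
        y = dataset.y[rows]
        keep = y >= 0
        self._est.fit(self._matrix(dataset, rows[keep]), y[keep])
        return self

    def predict(self, dataset, rows):
        rows = np.asarray(rows, dtype=np.intp)
        return np.asarray(self._est.predict(self._matrix(dataset, rows)), dtype=np.int64)


class LearnerRegistry:
    """Maps learner keys to constructors with declared parameter names."""

    def __init__(self):
        self._entries: dict[str, tuple] = {}

    def register(self, key: str, factory, param_names):
        """``factory(params: dict, seed: int | None) -> learner``."""
        if key in self._entries:
            raise LearnerError(f"learner key {key!r} already registered")
        self._entries[key] = (factory, frozenset(param_names))

    def keys(self):
        return sorted(self._entries)

    def build(self, key: str, params: dict, seed: int | None = None):
        if key not in self._entries:
            raise LearnerError(
                f"unknown learner {key!r}; registered: {', '.join(self.keys())}"
            )
        factory, allowed = self._entries[key]
        unknown = set(params) - allowed
        if unknown:
            raise LearnerError(
                f"unknown hyper-parameter(s) {sorted(unknown)} for learner "
                f"{key!r}; accepted: {sorted(allowed)}"
            )
        return factory(params, seed)

    def register_sklearn(self, key: str, estimator_factory, param_names):
        """Register an sklearn-style estimator class under ``key``."""
        self.register(
            key,
            lambda params, seed: SklearnAdapter(estimator_factory, params, seed),
            param_names,
        )


def default_registry() -> LearnerRegistry:
    reg = LearnerRegistry()
    reg.register("zeror", lambda params, seed: ZeroR(**_numeric_params(params)), ())
    reg.register("knn", lambda params, seed: KNearestNeighbours(**params), ("k",))
    reg.register("stump", lambda params, seed: DecisionStump(**params), ("min_leaf",))
    return reg


def _numeric_params(params):
    return {k: _coerce_number(v) for k, v in params.items()}
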