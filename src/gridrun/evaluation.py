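"""Cross-validation engines and metric computation.

Three strategies produce an :class:`EvaluationResult` for one concrete
experiment:

* leave-one-out cross-validation (LOOCV): n folds of size 1;
* k-fold cross-validation, optionally stratified (shuffle within each
  class, deal round-robin to folds so per-class counts differ by at most
  one — and, because the dealing pointer carries across classes, overall
  fold sizes do too);
* a single seeded train/test percentage split.

Cross-validated predictions are pooled into one confusion matrix
(micro aggregation) rather than averaged per fold, so every reported
number is an exact function of the individual predictions.

Rows whose class label is missing cannot be scored and are excluded from
evaluation entirely (they are neither trained on nor predicted).  A fold
whose training set happens to lack some class is still legal: the learner
simply never predicts that level, and its held-out instances score as
errors.

Fold assignment is a pure function of (n, k, seed, stratified, labels),
identical across platforms and worker counts — the property that makes
parallel and resumed runs reproduce serial ones exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np

from .spec_schema import EvaluationSpec

__all__ = [
    "EvaluationError",
    "EvaluationResult",
    "Metrics",
    "fold_assignment",
    "loocv",
    "kfold",
    "percentage_split",
    "compute_metrics",
    "evaluate_config",
]


class EvaluationError(Exception):
    pass


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    kappa: float
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]


@dataclass
class EvaluationResult:
    experiment_id: str
    n_instances: int
    class_levels: tuple[str, ...]
    confusion: np.ndarray  # rows = truth, columns = predicted
    metrics: Metrics
    strategy: EvaluationSpec | None = None
    status: str = "success"
    error_text: str | None = None

    def __eq__(self, other):
        if not isinstance(other, EvaluationResult):
            return NotImplemented
        return (
            self.experiment_id == other.experiment_id
            and self.n_instances == other.n_instances
            and self.class_levels == other.class_levels
            and np.array_equal(self.confusion, other.confusion)
            and self.metrics == other.metrics
            and self.strategy == other.strategy
            and self.status == other.status
        )


def compute_metrics(confusion) -> Metrics:
    """Accuracy, per-class precision/recall/F1 and Cohen's kappa.

    Zero-denominator conventions: precision and recall are 0 when their
    denominator is 0; F1 is 0 when precision + recall is 0; kappa is 0
    when the expected agreement p_e equals 1 (single-class degenerate
    matrix).
    """
    conf = np.asarray(confusion, dtype=np.float64)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise EvaluationError("confusion matrix must be square")
    if (conf < 0).any():
        raise EvaluationError("confusion matrix counts must be non-negative")
    total = conf.sum()
    if total == 0:
        raise EvaluationError("confusion matrix is empty")

    tp = np.diag(conf)
    row = conf.sum(axis=1)  # truth marginals (TP + FN)
    col = conf.sum(axis=0)  # prediction marginals (TP + FP)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)

    p_o = tp.sum() / total
    p_e = float((row * col).sum()) / (total * total)
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    return Metrics(
        accuracy=float(p_o),
        kappa=float(kappa),
        precision=tuple(map(float, precision)),
        recall=tuple(map(float, recall)),
        f1=tuple(map(float, f1)),
    )


def fold_assignment(labels, k: int, seed: int, stratified: bool) -> np.ndarray:
    """Assign each of n rows to a fold in [0, k).

    Unstratified: seeded shuffle, deal round-robin.  Stratified: shuffle
    within each class and deal round-robin, carrying the fold pointer
    across classes so overall fold sizes stay within one of each other.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if not 2 <= k <= n:
        raise EvaluationError(f"k must lie in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    if not stratified:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
        return folds
    pointer = 0
    classes = np.unique(labels)
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        idx = idx[rng.permutation(len(idx))]
        folds[idx] = (pointer + np.arange(len(idx))) % k
        pointer = (pointer + len(idx)) % k
    return folds


def _labelled_rows(dataset) -> np.ndarray:
    return np.nonzero(dataset.y >= 0)[0]


def _score_folds(dataset, learner_builder, rows, folds, k) -> np.ndarray:
    c = len(dataset.class_levels)
    conf = np.zeros((c, c), dtype=np.int64)
    y = dataset.y
    for f in range(k):
        test = rows[folds == f]
        train = rows[folds != f]
        if len(test) == 0:
            continue
        learner = learner_builder()
        learner.fit(dataset, train)
        preds = learner.predict(dataset, test)
        np.add.at(conf, (y[test], preds), 1)
    return conf


def loocv(dataset, learner_builder, experiment_id: str = "") -> EvaluationResult:
    """Leave-one-out: fit on all labelled rows but one, predict the one."""
    rows = _labelled_rows(dataset)
    n = len(rows)
    if n < 2:
        raise EvaluationError(f"LOOCV needs at least 2 labelled rows, got {n}")
    folds = np.arange(n)
    conf = _score_folds(dataset, learner_builder, rows, folds, n)
    return _wrap(experiment_id, dataset, conf, EvaluationSpec(strategy="loocv"))


def kfold(
    dataset,
    learner_builder,
    k: int,
    seed: int = 0,
    stratified: bool = True,
    experiment_id: str = "",
) -> EvaluationResult:
    rows = _labelled_rows(dataset)
    folds = fold_assignment(dataset.y[rows], k, seed, stratified)
    conf = _score_folds(dataset, learner_builder, rows, folds, k)
    return _wrap(
        experiment_id,
        dataset,
        conf,
        EvaluationSpec(strategy="kfold", k=k, stratified=stratified, eval_seed=seed),
    )


def percentage_split(
    dataset,
    learner_builder,
    train_fraction: float,
    seed: int = 0,
    experiment_id: str = "",
) -> EvaluationResult:
    """Single seeded shuffle; first floor(n * fraction) rows train, rest test."""
    frac = float(train_fraction)
    if not 0 < frac < 1:
        raise EvaluationError(f"train fraction must lie in (0,1), got {frac}")
    rows = _labelled_rows(dataset)
    n = len(rows)
    n_train = int(np.floor(n * frac))
    if n_train < 1 or n_train >= n:
        raise EvaluationError(
            f"split of {n} rows at fraction {frac} leaves an empty partition"
        )
    rng = np.random.default_rng(seed)
    perm = rows[rng.permutation(n)]
    train, test = perm[:n_train], perm[n_train:]
    learner = learner_builder()
    learner.fit(dataset, train)
    preds = learner.predict(dataset, test)
    c = len(dataset.class_levels)
    conf = np.zeros((c, c), dtype=np.int64)
    np.add.at(conf, (dataset.y[test], preds), 1)
    return _wrap(
        experiment_id,
        dataset,
        conf,
        EvaluationSpec(
            strategy="split",
            train_fraction=Decimal(str(train_fraction)),
            eval_seed=seed,
        ),
    )


def _wrap(experiment_id, dataset, conf, strategy) -> EvaluationResult:
    return EvaluationResult(
        experiment_id=experiment_id,
        n_instances=int(conf.sum()),
        class_levels=dataset.class_levels,
        confusion=conf,
        metrics=compute_metrics(conf),
        strategy=strategy,
    )


def evaluate_config(dataset, config, registry) -> EvaluationResult:
    """Run one concrete experiment configuration against a dataset.

    The learner is rebuilt for every fold from the config's parameters;
    any stochastic learner receives the config's derived seed, so the
    result depends only on (dataset, config), never on scheduling.
    """
    builder = lambda: registry.build(
        config.algorithm_key, config.params, seed=config.derived_seed
    )
    ev = config.evaluation
    if ev.strategy == "loocv":
        result = loocv(dataset, builder, config.experiment_id)
    elif ev.strategy == "kfold":
        result = kfold(
            dataset,
            builder,
            k=ev.k,
            seed=ev.eval_seed or 0,
            stratified=True if ev.stratified is None else ev.stratified,
            experiment_id=config.experiment_id,
        )
    elif ev.strategy == "split":
        result = percentage_split(
            dataset,
            builder,
            train_fraction=float(ev.train_fraction),
            seed=ev.eval_seed or 0,
            experiment_id=config.experiment_id,
        )
    else:
        raise EvaluationError(f"unknown strategy {ev.strategy!r}")
    result.strategy = ev
    return result
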