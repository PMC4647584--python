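"""Expand a specification into the full Cartesian grid of experiments.

Each algorithm's ranged hyper-parameters are materialised (value sets in
declaration order, intervals by the index formula ``v_i = start + i*step``)
and crossed; every grid point becomes one independent
:class:`ExperimentConfig` carrying a content-addressed identifier and a
derived random seed.  Content digests, not ordinal indices, make resuming
an interrupted run safe: editing the spec changes the ids, so stale result
files can never be mistaken for current ones.

Grid order is deterministic: algorithms in declaration order, and within
an algorithm the last-declared parameter varies fastest (odometer order).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import re
from dataclasses import dataclass
from decimal import Decimal

from .spec_schema import (
    EvaluationSpec,
    ExperimentSpec,
    ParameterRange,
    Scalar,
    format_scalar,
)

__all__ = [
    "ExperimentConfig",
    "RangeError",
    "materialise_range",
    "expand",
    "experiment_id",
    "derive_seed",
]

_ID_RE = re.compile(r"^[A-Za-z0-9._-]+$")
_UNSAFE_RE = re.compile(r"[^A-Za-z0-9._-]")


class RangeError(ValueError):
    """A ParameterRange violates its invariants."""


@dataclass(frozen=True)
class ExperimentConfig:
    """One fully-concrete experiment: algorithm + exact parameter assignment."""

    experiment_id: str
    algorithm_key: str
    params: dict[str, Scalar]
    evaluation: EvaluationSpec
    dataset_ref: str
    derived_seed: int


def materialise_range(rng: ParameterRange) -> tuple[Scalar, ...]:
    """Turn a range into its ordered concrete values.

    Interval values are computed by index (``start + i*step``), never by
    accumulation, and the end point is included when it lies on the
    lattice within a relative tolerance of 1e-9 of the step.  With
    Decimal arithmetic the tolerance is moot, but it keeps the contract
    honest for callers constructing ranges from floats.
    """
    if rng.form == "value_set":
        if not rng.values:
            raise RangeError("value set is empty")
        if len(set(map(format_scalar, rng.values))) != len(rng.values):
            raise RangeError("value set contains duplicates")
        return tuple(rng.values)
    if rng.form != "interval":
        raise RangeError(f"unknown range form {rng.form!r}")
    start, step, end = rng.start, rng.step, rng.end
    if step == 0:
        raise RangeError("interval step must be non-zero")
    if start != end and ((end - start > 0) != (step > 0)):
        raise RangeError(
            f"step sign does not move start={start} towards end={end}"
        )
    eps = abs(step) * Decimal("1e-9") if isinstance(step, Decimal) else abs(step) * 1e-9
    values: list[Scalar] = []
    i = 0
    while True:
        v = start + i * step
        if step > 0 and v > end + eps:
            break
        if step < 0 and v < end - eps:
            break
        values.append(v)
        i += 1
    return tuple(values)


def _canonical_params(params: dict[str, Scalar]) -> dict[str, str]:
    return {name: format_scalar(v) for name, v in params.items()}


def _evaluation_descriptor(ev: EvaluationSpec) -> dict:
    return {
        "strategy": ev.strategy,
        "k": ev.k,
        "stratified": ev.stratified,
        "train_fraction": None
        if ev.train_fraction is None
        else format_scalar(ev.train_fraction),
        "eval_seed": ev.eval_seed,
    }


def experiment_id(
    dataset_ref: str,
    algorithm_key: str,
    params: dict[str, Scalar],
    evaluation: EvaluationSpec,
) -> str:
    """Deterministic filesystem-safe identifier for one experiment.

    A readable slug (algorithm plus parameter assignment, ``.`` mapped to
    ``p`` so values stay shell- and glob-friendly) suffixed with an
    8-hex-digit digest of the full content, so ids are stable across
    platforms and unique across grid points.
    """
    parts = [_UNSAFE_RE.sub("-", algorithm_key) or "alg"]
    for name, value in params.items():
        text = format_scalar(value).replace(".", "p")
        parts.append(_UNSAFE_RE.sub("-", f"{name}-{text}"))
    payload = json.dumps(
        {
            "dataset": dataset_ref,
            "algorithm": algorithm_key,
            "params": _canonical_params(params),
            "evaluation": _evaluation_descriptor(evaluation),
        },
        sort_keys=True,
        separators=(",", ":"),
    )
    digest = hashlib.sha256(payload.encode("utf-8")).hexdigest()[:8]
    slug = "__".join(parts + [digest])
    assert _ID_RE.match(slug)
    return slug


def derive_seed(master_seed: int, experiment_id: str) -> int:
    """Stable per-experiment seed in [0, 2^31): digest of master ∥ id.

    Independent of execution order and worker count, so parallel and
    serial runs of the same grid are bit-identical.
    """
    if master_seed < 0:
        raise ValueError("master_seed must be >= 0")
    digest = hashlib.sha256(
        f"{master_seed}|{experiment_id}".encode("utf-8")
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def expand(spec: ExperimentSpec) -> list[ExperimentConfig]:
    """Materialise every algorithm's ranges and build the Cartesian grid.

    Total size is ``sum over algorithms of prod over ranges of |range|``
    (an algorithm with no ranges contributes exactly one configuration).
    """
    configs: list[ExperimentConfig] = []
    for alg in spec.algorithms:
        names = list(alg.ranged_params)
        axes = [materialise_range(alg.ranged_params[n]) for n in names]
        for combo in itertools.product(*axes):
            params: dict[str, Scalar] = dict(alg.fixed_params)
            params.update(zip(names, combo))
            eid = experiment_id(
                spec.dataset_ref, alg.key, params, spec.evaluation
            )
            configs.append(
                ExperimentConfig(
                    experiment_id=eid,
                    algorithm_key=alg.key,
                    params=params,
                    evaluation=spec.evaluation,
                    dataset_ref=spec.dataset_ref,
                    derived_seed=derive_seed(spec.master_seed, eid),
                )
            )
    return configs
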