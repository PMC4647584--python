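"""Result-file and summary serialisation.

Each experiment produces one sectioned key–value text file that is both
human-readable and machine-parsable.  Everything above the
``[provenance]`` section is the *payload*; the provenance section holds
the wall-clock duration (informational only) and a SHA-256 digest of the
payload.  The digest is the completion footer: a file is "successfully
complete" iff its digest matches its payload, so a crash mid-write can
never leave a valid-looking partial result.

Floats are written with ``repr`` (shortest round-trip form), so parsing a
result file recovers every numeric field exactly and re-running an
experiment reproduces its file byte-for-byte apart from the duration
line.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass

import numpy as np

from .evaluation import EvaluationResult, Metrics
from .grid_expansion import ExperimentConfig
from .spec_schema import EvaluationSpec, ExperimentSpec, format_scalar, parse_scalar

__all__ = [
    "ExperimentOutcome",
    "ResultParseError",
    "render_result",
    "parse_result",
    "payload_digest",
    "write_summary",
]

PROVENANCE_HEADER = "[provenance]"


class ResultParseError(Exception):
    pass


@dataclass
class ExperimentOutcome:
    """Terminal state of one experiment: a result or an error record."""

    config: ExperimentConfig
    status: str  # "success" | "failed"
    result: EvaluationResult | None = None
    error_text: str | None = None
    duration_s: float = 0.0

    @property
    def experiment_id(self) -> str:
        return self.config.experiment_id


def _fmt_float(v: float) -> str:
    return repr(float(v))


def _strategy_lines(ev: EvaluationSpec) -> list[str]:
    lines = [f"strategy = {ev.strategy}"]
    if ev.strategy == "kfold":
        lines.append(f"k = {ev.k}")
        lines.append(f"stratified = {'true' if ev.stratified else 'false'}")
        lines.append(f"seed = {ev.eval_seed}")
    elif ev.strategy == "split":
        lines.append(f"fraction = {format_scalar(ev.train_fraction)}")
        lines.append(f"seed = {ev.eval_seed}")
    return lines


def render_result(outcome: ExperimentOutcome) -> str:
    """Serialise an outcome to sectioned key–value text with footer digest."""
    cfg = outcome.config
    lines: list[str] = ["[experiment]"]
    lines.append(f"id = {cfg.experiment_id}")
    lines.append(f"algorithm = {cfg.algorithm_key}")
    lines.append(f"dataset = {cfg.dataset_ref}")
    lines.append(f"derived_seed = {cfg.derived_seed}")
    for name, value in cfg.params.items():
        lines.append(f"param.{name} = {format_scalar(value)}")
    lines.append("[evaluation]")
    lines.extend(_strategy_lines(cfg.evaluation))
    lines.append("[status]")
    lines.append(f"status = {outcome.status}")
    if outcome.status == "failed":
        lines.append("error = " + (outcome.error_text or "").replace("\n", "\\n"))
    else:
        r = outcome.result
        lines.append("[confusion]")
        lines.append("levels = " + ",".join(r.class_levels))
        for level, row in zip(r.class_levels, r.confusion):
            lines.append(f"row.{level} = " + ",".join(str(int(v)) for v in row))
        lines.append("[metrics]")
        lines.append(f"n_instances = {r.n_instances}")
        lines.append(f"accuracy = {_fmt_float(r.metrics.accuracy)}")
        lines.append(f"kappa = {_fmt_float(r.metrics.kappa)}")
        for i, level in enumerate(r.class_levels):
            lines.append(f"precision.{level} = {_fmt_float(r.metrics.precision[i])}")
            lines.append(f"recall.{level} = {_fmt_float(r.metrics.recall[i])}")
            lines.append(f"f1.{level} = {_fmt_float(r.metrics.f1[i])}")
    payload = "\n".join(lines) + "\n"
    return (
        payload
        + f"{PROVENANCE_HEADER}\n"
        + f"duration_s = {_fmt_float(outcome.duration_s)}\n"
        + f"payload_sha256 = {payload_digest(payload)}\n"
    )


def payload_digest(payload: str) -> str:
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def split_payload(text: str) -> tuple[str, dict]:
    """Split a result file into (payload, provenance fields)."""
    marker = f"{PROVENANCE_HEADER}\n"
    pos = text.find(marker)
    if pos < 0:
        raise ResultParseError("missing provenance section")
    payload = text[: pos]
    prov: dict[str, str] = {}
    for line in text[pos + len(marker):].splitlines():
        if " = " in line:
            k, v = line.split(" = ", 1)
            prov[k.strip()] = v.strip()
    return payload, prov


def parse_result(text: str) -> ExperimentOutcome:
    """Parse a result file back into an outcome (inverse of render_result).

    Raises :class:`ResultParseError` if the file is structurally broken
    or its completion footer does not match the payload.
    """
    payload, prov = split_payload(text)
    if prov.get("payload_sha256") != payload_digest(payload):
        raise ResultParseError("completion footer digest does not match payload")

    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in payload.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif " = " in line and current is not None:
            k, v = line.split(" = ", 1)
            current[k] = v
        else:
            raise ResultParseError(f"unparsable line {line!r}")

    try:
        exp = sections["experiment"]
        ev_sec = sections["evaluation"]
        status = sections["status"]["status"]
    except KeyError as exc:
        raise ResultParseError(f"missing section/field: {exc}") from None

    params = {
        k[len("param."):]: parse_scalar(v)
        for k, v in exp.items()
        if k.startswith("param.")
    }
    strategy = ev_sec["strategy"]
    ev = EvaluationSpec(
        strategy=strategy,
        k=int(ev_sec["k"]) if strategy == "kfold" else None,
        stratified=(ev_sec.get("stratified") == "true") if strategy == "kfold" else None,
        train_fraction=parse_scalar(ev_sec["fraction"]) if strategy == "split" else None,
        eval_seed=int(ev_sec["seed"]) if strategy in ("kfold", "split") else None,
    )
    config = ExperimentConfig(
        experiment_id=exp["id"],
        algorithm_key=exp["algorithm"],
        params=params,
        evaluation=ev,
        dataset_ref=exp["dataset"],
        derived_seed=int(exp["derived_seed"]),
    )

    result = None
    error_text = None
    if status == "failed":
        error_text = sections["status"].get("error", "").replace("\\n", "\n")
    else:
        conf_sec = sections["confusion"]
        met = sections["metrics"]
        levels = tuple(conf_sec["levels"].split(","))
        confusion = np.array(
            [
                [int(v) for v in conf_sec[f"row.{level}"].split(",")]
                for level in levels
            ],
            dtype=np.int64,
        )
        metrics = Metrics(
            accuracy=float(met["accuracy"]),
            kappa=float(met["kappa"]),
            precision=tuple(float(met[f"precision.{lv}"]) for lv in levels),
            recall=tuple(float(met[f"recall.{lv}"]) for lv in levels),
            f1=tuple(float(met[f"f1.{lv}"]) for lv in levels),
        )
        result = EvaluationResult(
            experiment_id=exp["id"],
            n_instances=int(met["n_instances"]),
            class_levels=levels,
            confusion=confusion,
            metrics=metrics,
            strategy=ev,
            status="success",
        )

    return ExperimentOutcome(
        config=config,
        status=status,
        result=result,
        error_text=error_text,
        duration_s=float(prov.get("duration_s", 0.0)),
    )


def _strategy_descriptor(ev: EvaluationSpec) -> str:
    if ev.strategy == "kfold":
        strat = "stratified" if (ev.stratified in (None, True)) else "unstratified"
        return f"kfold(k={ev.k},{strat},seed={ev.eval_seed})"
    if ev.strategy == "split":
        return f"split(fraction={format_scalar(ev.train_fraction)},seed={ev.eval_seed})"
    return "loocv"


def write_summary(outcomes: list[ExperimentOutcome], spec: ExperimentSpec) -> str:
    """Render the run summary CSV: one row per experiment in grid order.

    A trailing comment block names the best configuration per algorithm,
    ranked by accuracy over successful experiments (ties resolved to the
    first in grid order).
    """
    param_names: list[str] = []
    for alg in spec.algorithms:
        for name in list(alg.fixed_params) + list(alg.ranged_params):
            if name not in param_names:
                param_names.append(name)

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["experiment_id", "algorithm"]
        + param_names
        + ["strategy", "n_instances", "accuracy", "kappa", "status"]
    )
    for o in outcomes:
        row = [o.experiment_id, o.config.algorithm_key]
        for name in param_names:
            v = o.config.params.get(name)
            row.append("" if v is None else format_scalar(v))
        row.append(_strategy_descriptor(o.config.evaluation))
        if o.status == "success":
            row += [
                o.result.n_instances,
                _fmt_float(o.result.metrics.accuracy),
                _fmt_float(o.result.metrics.kappa),
                "success",
            ]
        else:
            row += ["", "", "", "failed"]
        writer.writerow(row)

    for alg in spec.algorithms:
        best = None
        for o in outcomes:
            if o.config.algorithm_key != alg.key or o.status != "success":
                continue
            if best is None or o.result.metrics.accuracy > best.result.metrics.accuracy:
                best = o
        if best is None:
            buf.write(f"# best {alg.key}: none (no successful experiment)\n")
        else:
            params = ",".join(
                f"{k}={format_scalar(v)}" for k, v in best.config.params.items()
            )
            buf.write(
                f"# best {alg.key}: {best.experiment_id} "
                f"params[{params}] accuracy={_fmt_float(best.result.metrics.accuracy)}\n"
            )
    return buf.getvalue()
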