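"""Succinct XML experiment specifications: parse, validate, serialise.

An experiment specification names a dataset, an evaluation strategy, one
or more learning algorithms (each with fixed and/or ranged hyper-parameters)
and an output directory.  The schema is deliberately tiny — one element per
concept — so a non-programmer can write a multi-algorithm grid search in a
dozen lines:

    <experiments>
      <dataset path="iris.arff" class="last"/>
      <evaluation strategy="loocv"/>
      <algorithm key="knn">
        <param name="k" start="1" step="1" end="10"/>
      </algorithm>
      <output dir="results"/>
    </experiments>

Parsing is strict: unknown elements and attributes are rejected with a
message naming the offending node.  A typo in a hyper-parameter name would
otherwise silently change the experiment grid, which is exactly the kind of
error a declarative front-end exists to prevent.

Numbers are carried as :class:`decimal.Decimal` (or ``int``) so that range
end-points and step sizes survive serialisation round trips exactly; they
are converted to floats only at the point a learner consumes them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import Union

from lxml import etree

__all__ = [
    "Scalar",
    "ParameterRange",
    "EvaluationSpec",
    "AlgorithmSpec",
    "ExperimentSpec",
    "Violation",
    "SpecError",
    "SpecParseError",
    "SchemaError",
    "SpecValidationError",
    "parse_spec",
    "validate_spec",
    "write_spec",
    "parse_scalar",
    "format_scalar",
]

Scalar = Union[int, bool, Decimal, str]

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")

STRATEGIES = ("loocv", "kfold", "split")


class SpecError(Exception):
    """Base class for specification errors."""


class SpecParseError(SpecError):
    """Malformed XML (not well-formed)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None and f"line {line}" not in message:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(SpecError):
    """Well-formed XML that does not conform to the experiment schema."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SpecValidationError(SpecError):
    """Raised when an operation refuses an invalid ExperimentSpec."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__(
            "invalid experiment spec: "
            + "; ".join(f"[{v.code}] {v.message}" for v in violations)
        )


def parse_scalar(text: str) -> Scalar:
    """Parse an attribute token into int, Decimal, bool or str."""
    t = text.strip()
    if t in ("true", "false"):
        return t == "true"
    if _NUMERIC_RE.match(t):
        try:
            return int(t)
        except ValueError:
            pass
        try:
            return Decimal(t)
        except InvalidOperation:  # pragma: no cover - regex guards this
            pass
    return t


def _fmt_decimal(d: Decimal) -> str:
    # normalize() strips trailing zeros; 'f' format avoids E notation
    return format(d.normalize(), "f")


def format_scalar(v: Scalar) -> str:
    """Canonical text form of a scalar (inverse of :func:`parse_scalar`)."""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, Decimal):
        return _fmt_decimal(v)
    return str(v)


@dataclass(frozen=True)
class ParameterRange:
    """Either an explicit ordered value set or a numeric start/step/end interval."""

    form: str  # "value_set" | "interval"
    values: tuple[Scalar, ...] = ()
    start: Scalar | None = None
    step: Scalar | None = None
    end: Scalar | None = None

    @classmethod
    def value_set(cls, values) -> "ParameterRange":
        return cls(form="value_set", values=tuple(values))

    @classmethod
    def interval(cls, start, step, end) -> "ParameterRange":
        return cls(form="interval", start=start, step=step, end=end)


@dataclass(frozen=True)
class EvaluationSpec:
    """How each experiment is scored.

    strategy
        ``loocv`` (leave-one-out), ``kfold`` or ``split`` (single
        train/test partition).
    k, stratified, eval_seed
        k-fold only; stratified dealing preserves class proportions
        per fold.
    train_fraction, eval_seed
        split only.
    """

    strategy: str
    k: int | None = None
    stratified: bool | None = None
    train_fraction: Decimal | None = None
    eval_seed: int | None = None


@dataclass(frozen=True)
class AlgorithmSpec:
    key: str
    fixed_params: dict[str, Scalar] = field(default_factory=dict)
    ranged_params: dict[str, ParameterRange] = field(default_factory=dict)


@dataclass(frozen=True)
class ExperimentSpec:
    dataset_ref: str
    evaluation: EvaluationSpec
    algorithms: tuple[AlgorithmSpec, ...]
    output_dir: str
    class_attribute: str = "last"
    workers: int | str = "auto"  # "auto" = logical cores - 1
    master_seed: int = 0


@dataclass(frozen=True)
class Violation:
    code: str
    message: str


# --------------------------------------------------------------------------
# parsing

_ALLOWED_CHILDREN = {"dataset", "evaluation", "algorithm", "output", "run"}


def _line(el) -> int | None:
    return getattr(el, "sourceline", None)


def _check_attrs(el, allowed: set[str], required: set[str]) -> None:
    for name in el.attrib:
        if name not in allowed:
            raise SchemaError(
                f"unknown attribute '{name}' on <{el.tag}>", line=_line(el)
            )
    for name in required:
        if name not in el.attrib:
            raise SchemaError(
                f"<{el.tag}> requires attribute '{name}'", line=_line(el)
            )


def _check_no_text(el) -> None:
    if el.text and el.text.strip():
        raise SchemaError(
            f"unexpected text content in <{el.tag}>", line=_line(el)
        )


def _element_children(el):
    for child in el:
        if isinstance(child.tag, str):  # skip comments / PIs
            yield child
        if child.tail and child.tail.strip():
            raise SchemaError(
                f"unexpected text content in <{el.tag}>", line=_line(child)
            )


def _parse_int_attr(el, name: str, minimum: int | None = None) -> int:
    raw = el.get(name)
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"attribute '{name}' on <{el.tag}> must be an integer, got {raw!r}",
            line=_line(el),
        ) from None
    if minimum is not None and value < minimum:
        raise SchemaError(
            f"attribute '{name}' on <{el.tag}> must be >= {minimum}, got {value}",
            line=_line(el),
        )
    return value


def _parse_decimal_attr(el, name: str) -> Decimal:
    raw = el.get(name)
    if raw is None or not _NUMERIC_RE.match(raw.strip()):
        raise SchemaError(
            f"attribute '{name}' on <{el.tag}> must be a number, got {raw!r}",
            line=_line(el),
        )
    return Decimal(raw.strip())


def _parse_number_attr(el, name: str) -> Scalar:
    v = parse_scalar(el.get(name))
    if not isinstance(v, (int, Decimal)) or isinstance(v, bool):
        raise SchemaError(
            f"attribute '{name}' on <{el.tag}> must be a number, got {el.get(name)!r}",
            line=_line(el),
        )
    return v


def _parse_evaluation(el) -> EvaluationSpec:
    strategy = el.get("strategy")
    if strategy not in STRATEGIES:
        raise SchemaError(
            f"<evaluation> strategy must be one of {'/'.join(STRATEGIES)}, "
            f"got {strategy!r}",
            line=_line(el),
        )
    if strategy == "loocv":
        _check_attrs(el, {"strategy"}, {"strategy"})
        return EvaluationSpec(strategy="loocv")
    if strategy == "kfold":
        _check_attrs(el, {"strategy", "k", "stratified", "seed"}, {"strategy", "k"})
        stratified = el.get("stratified", "true")
        if stratified not in ("true", "false"):
            raise SchemaError(
                f"attribute 'stratified' must be 'true' or 'false', got {stratified!r}",
                line=_line(el),
            )
        return EvaluationSpec(
            strategy="kfold",
            k=_parse_int_attr(el, "k"),
            stratified=stratified == "true",
            eval_seed=_parse_int_attr(el, "seed") if "seed" in el.attrib else 0,
        )
    # split
    _check_attrs(el, {"strategy", "fraction", "seed"}, {"strategy", "fraction"})
    return EvaluationSpec(
        strategy="split",
        train_fraction=_parse_decimal_attr(el, "fraction"),
        eval_seed=_parse_int_attr(el, "seed") if "seed" in el.attrib else 0,
    )


def _parse_param(el, algorithm_key: str):
    _check_attrs(
        el, {"name", "value", "values", "start", "step", "end"}, {"name"}
    )
    _check_no_text(el)
    for child in _element_children(el):
        raise SchemaError(
            f"unknown element <{child.tag}> inside <param>", line=_line(child)
        )
    name = el.get("name")
    has_value = "value" in el.attrib
    has_values = "values" in el.attrib
    has_interval = any(a in el.attrib for a in ("start", "step", "end"))
    n_forms = sum([has_value, has_values, has_interval])
    if n_forms == 0:
        raise SchemaError(
            f"<param name={name!r}> needs one of value=, values= or "
            "start=/step=/end=",
            line=_line(el),
        )
    if n_forms > 1:
        raise SchemaError(
            f"<param name={name!r}> mixes fixed/value-set/interval forms",
            line=_line(el),
        )
    if has_value:
        return name, parse_scalar(el.get("value")), None
    if has_values:
        tokens = [t for t in el.get("values").split(",")]
        if not any(t.strip() for t in tokens):
            raise SchemaError(
                f"<param name={name!r}> has an empty values= list", line=_line(el)
            )
        return name, None, ParameterRange.value_set(parse_scalar(t) for t in tokens)
    missing = [a for a in ("start", "step", "end") if a not in el.attrib]
    if missing:
        raise SchemaError(
            f"<param name={name!r}> interval needs start=, step= and end= "
            f"(missing {', '.join(missing)})",
            line=_line(el),
        )
    return name, None, ParameterRange.interval(
        _parse_number_attr(el, "start"),
        _parse_number_attr(el, "step"),
        _parse_number_attr(el, "end"),
    )


def _parse_algorithm(el) -> AlgorithmSpec:
    _check_attrs(el, {"key"}, {"key"})
    _check_no_text(el)
    key = el.get("key")
    fixed: dict[str, Scalar] = {}
    ranged: dict[str, ParameterRange] = {}
    for child in _element_children(el):
        if child.tag != "param":
            raise SchemaError(
                f"unknown element <{child.tag}> inside <algorithm>",
                line=_line(child),
            )
        name, value, rng = _parse_param(child, key)
        if name in fixed or name in ranged:
            raise SchemaError(
                f"duplicate parameter {name!r} in algorithm {key!r}",
                line=_line(child),
            )
        if rng is None:
            fixed[name] = value
        else:
            ranged[name] = rng
    return AlgorithmSpec(key=key, fixed_params=fixed, ranged_params=ranged)


def parse_spec(xml_text: str) -> ExperimentSpec:
    """Parse an XML experiment specification.

    Raises :class:`SpecParseError` for malformed XML (with the line
    number) and :class:`SchemaError` for well-formed documents that do
    not fit the schema — including any unrecognised element or attribute.
    """
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise SpecParseError(str(exc), line=exc.lineno) from None

    if root.tag != "experiments":
        raise SchemaError(
            f"root element must be <experiments>, got <{root.tag}>",
            line=_line(root),
        )
    _check_attrs(root, set(), set())
    _check_no_text(root)

    seen: dict[str, object] = {}
    algorithms: list[AlgorithmSpec] = []
    for child in _element_children(root):
        tag = child.tag
        if tag not in _ALLOWED_CHILDREN:
            raise SchemaError(f"unknown element <{tag}>", line=_line(child))
        if tag != "algorithm" and tag in seen:
            raise SchemaError(f"duplicate element <{tag}>", line=_line(child))
        if tag == "dataset":
            _check_attrs(child, {"path", "class"}, {"path"})
            _check_no_text(child)
            seen["dataset"] = (child.get("path"), child.get("class", "last"))
        elif tag == "evaluation":
            seen["evaluation"] = _parse_evaluation(child)
        elif tag == "algorithm":
            algorithms.append(_parse_algorithm(child))
        elif tag == "output":
            _check_attrs(child, {"dir"}, {"dir"})
            _check_no_text(child)
            seen["output"] = child.get("dir")
        elif tag == "run":
            _check_attrs(child, {"workers", "seed"}, set())
            _check_no_text(child)
            workers: int | str = "auto"
            if "workers" in child.attrib:
                raw = child.get("workers")
                workers = "auto" if raw == "auto" else _parse_int_attr(child, "workers")
            master_seed = (
                _parse_int_attr(child, "seed", minimum=0)
                if "seed" in child.attrib
                else 0
            )
            seen["run"] = (workers, master_seed)

    for mandatory in ("dataset", "evaluation", "output"):
        if mandatory not in seen:
            raise SchemaError(f"missing mandatory element <{mandatory}>")
    if not algorithms:
        raise SchemaError("at least one <algorithm> element is required")

    dataset_ref, class_attribute = seen["dataset"]
    workers, master_seed = seen.get("run", ("auto", 0))
    return ExperimentSpec(
        dataset_ref=dataset_ref,
        class_attribute=class_attribute,
        evaluation=seen["evaluation"],
        algorithms=tuple(algorithms),
        output_dir=seen["output"],
        workers=workers,
        master_seed=master_seed,
    )


# --------------------------------------------------------------------------
# validation


def _validate_range(prefix: str, rng: ParameterRange, out: list[Violation]) -> None:
    if rng.form == "value_set":
        if not rng.values:
            out.append(Violation("RANGE_EMPTY", f"{prefix}: empty value set"))
        elif len(set(map(format_scalar, rng.values))) != len(rng.values):
            out.append(
                Violation("RANGE_DUP_VALUES", f"{prefix}: duplicate values")
            )
        return
    if rng.form != "interval":
        out.append(Violation("RANGE_FORM", f"{prefix}: unknown form {rng.form!r}"))
        return
    if rng.step == 0:
        out.append(Violation("RANGE_STEP_ZERO", f"{prefix}: interval step is zero"))
        return
    if rng.start != rng.end and ((rng.end - rng.start > 0) != (rng.step > 0)):
        out.append(
            Violation(
                "RANGE_DIRECTION",
                f"{prefix}: step sign does not move start={rng.start} "
                f"towards end={rng.end}",
            )
        )


def validate_spec(spec: ExperimentSpec) -> list[Violation]:
    """Check every type invariant; return violations rather than raising."""
    out: list[Violation] = []
    if not spec.dataset_ref:
        out.append(Violation("DATASET_EMPTY", "dataset reference is empty"))
    if not spec.class_attribute:
        out.append(Violation("CLASS_ATTRIBUTE_EMPTY", "class attribute is empty"))
    if not spec.output_dir:
        out.append(Violation("OUTPUT_EMPTY", "output directory is empty"))
    if spec.workers != "auto" and (
        not isinstance(spec.workers, int) or spec.workers < 1
    ):
        out.append(
            Violation("WORKERS_INVALID", f"workers must be >= 1 or 'auto', got {spec.workers!r}")
        )
    if spec.master_seed < 0:
        out.append(Violation("MASTER_SEED_NEGATIVE", "master seed must be >= 0"))
    if not spec.algorithms:
        out.append(Violation("NO_ALGORITHMS", "at least one algorithm is required"))

    ev = spec.evaluation
    if ev.strategy not in STRATEGIES:
        out.append(
            Violation("EVAL_STRATEGY", f"unknown evaluation strategy {ev.strategy!r}")
        )
    else:
        required = {
            "loocv": (),
            "kfold": ("k", "stratified", "eval_seed"),
            "split": ("train_fraction", "eval_seed"),
        }[ev.strategy]
        for f in ("k", "stratified", "train_fraction", "eval_seed"):
            present = getattr(ev, f) is not None
            if present and f not in required:
                out.append(
                    Violation(
                        "EVAL_FIELDS",
                        f"evaluation field {f!r} is not applicable to "
                        f"strategy {ev.strategy!r}",
                    )
                )
            if not present and f in required:
                out.append(
                    Violation(
                        "EVAL_FIELDS",
                        f"evaluation field {f!r} is required for "
                        f"strategy {ev.strategy!r}",
                    )
                )
        if ev.strategy == "kfold" and ev.k is not None and ev.k < 2:
            out.append(Violation("EVAL_K_INVALID", f"k must be >= 2, got {ev.k}"))
        if ev.strategy == "split" and ev.train_fraction is not None:
            if not (0 < ev.train_fraction < 1):
                out.append(
                    Violation(
                        "EVAL_FRACTION_INVALID",
                        f"train fraction must lie in (0,1), got {ev.train_fraction}",
                    )
                )
        if ev.eval_seed is not None and ev.eval_seed < 0:
            out.append(Violation("EVAL_SEED_NEGATIVE", "evaluation seed must be >= 0"))

    for alg in spec.algorithms:
        if not alg.key:
            out.append(Violation("ALGO_KEY_EMPTY", "algorithm key is empty"))
        clash = set(alg.fixed_params) & set(alg.ranged_params)
        if clash:
            out.append(
                Violation(
                    "PARAM_NAME_CLASH",
                    f"algorithm {alg.key!r}: parameters both fixed and ranged: "
                    f"{sorted(clash)}",
                )
            )
        for name, rng in alg.ranged_params.items():
            _validate_range(f"{alg.key}.{name}", rng, out)
    return out


# --------------------------------------------------------------------------
# serialisation


def write_spec(spec: ExperimentSpec) -> str:
    """Serialise a valid spec to canonical XML (one element per line).

    Elements that would merely restate defaults (``class="last"``, the
    whole ``<run>`` element when workers and seed are default) are
    omitted, so parse(write(s)) is structurally identical to ``s``.
    """
    violations = validate_spec(spec)
    if violations:
        raise SpecValidationError(violations)

    root = etree.Element("experiments")
    ds = etree.SubElement(root, "dataset")
    ds.set("path", spec.dataset_ref)
    if spec.class_attribute != "last":
        ds.set("class", spec.class_attribute)

    ev = spec.evaluation
    evel = etree.SubElement(root, "evaluation")
    evel.set("strategy", ev.strategy)
    if ev.strategy == "kfold":
        evel.set("k", str(ev.k))
        if ev.stratified is False:
            evel.set("stratified", "false")
        if ev.eval_seed:
            evel.set("seed", str(ev.eval_seed))
    elif ev.strategy == "split":
        evel.set("fraction", format_scalar(ev.train_fraction))
        if ev.eval_seed:
            evel.set("seed", str(ev.eval_seed))

    for alg in spec.algorithms:
        ael = etree.SubElement(root, "algorithm")
        ael.set("key", alg.key)
        for name, value in alg.fixed_params.items():
            pel = etree.SubElement(ael, "param")
            pel.set("name", name)
            pel.set("value", format_scalar(value))
        for name, rng in alg.ranged_params.items():
            pel = etree.SubElement(ael, "param")
            pel.set("name", name)
            if rng.form == "value_set":
                pel.set("values", ",".join(format_scalar(v) for v in rng.values))
            else:
                pel.set("start", format_scalar(rng.start))
                pel.set("step", format_scalar(rng.step))
                pel.set("end", format_scalar(rng.end))

    out = etree.SubElement(root, "output")
    out.set("dir", spec.output_dir)

    if spec.workers != "auto" or spec.master_seed != 0:
        run = etree.SubElement(root, "run")
        if spec.workers != "auto":
            run.set("workers", str(spec.workers))
        if spec.master_seed != 0:
            run.set("seed", str(spec.master_seed))

    return etree.tostring(root, pretty_print=True, encoding="unicode")
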