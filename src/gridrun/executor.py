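"""Fault-tolerant, parallel execution of an expanded experiment grid.

Each experiment writes its own result file the moment it finishes, via a
write-to-temp-then-rename commit, so an interrupted run leaves only
complete, verifiable files behind.  Resuming is a set difference: any
experiment whose content-addressed result file exists, parses and carries
a matching completion footer is skipped; everything else (absent, partial
or corrupt) runs again.  Because completion order under parallelism is
nondeterministic, "resume from the most recent success" is deliberately
implemented as this set difference rather than a linear cursor.

Every worker's randomness comes exclusively from the experiment's derived
seed, so results are bit-identical across worker counts and across
kill/resume cycles.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import time
import traceback
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, wait
from dataclasses import dataclass
from pathlib import Path

from . import reporting
from .dataset_io import load_dataset
from .evaluation import evaluate_config
from .grid_expansion import ExperimentConfig, expand
from .learners import LearnerRegistry, default_registry
from .reporting import ExperimentOutcome, parse_result, render_result
from .spec_schema import ExperimentSpec, SpecValidationError, validate_spec, write_spec

__all__ = [
    "ExecutorError",
    "StaleResultsError",
    "RefusingOverwriteError",
    "RunReport",
    "spec_digest",
    "plan_run",
    "execute",
    "commit_result",
    "is_complete",
    "resolve_workers",
    "run",
]

MANIFEST_NAME = "manifest.json"
SUMMARY_NAME = "summary.csv"
RESULT_SUFFIX = ".result"
TMP_PREFIX = ".tmp-"


class ExecutorError(Exception):
    pass


class StaleResultsError(ExecutorError):
    """Output directory holds results produced by a different spec."""


class RefusingOverwriteError(ExecutorError):
    """Fresh (non-resume) run would clobber existing result files."""


@dataclass
class RunReport:
    """Outcome of a full (or interrupted) run over the expanded grid."""

    outcomes: list[ExperimentOutcome]  # grid order; None entries never occur
    executed: int  # experiments actually run this invocation
    skipped: int  # satisfied from existing result files
    interrupted: bool  # stop_after fired before the grid finished
    output_dir: Path

    @property
    def n_failed(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "failed")


def spec_digest(spec: ExperimentSpec) -> str:
    return hashlib.sha256(write_spec(spec).encode("utf-8")).hexdigest()


def resolve_workers(workers) -> int:
    """'auto' = logical cores minus one, floor 1."""
    if workers == "auto":
        return max(1, (os.cpu_count() or 2) - 1)
    workers = int(workers)
    if workers < 1:
        raise ExecutorError(f"worker count must be >= 1, got {workers}")
    return workers


def _result_path(output_dir: Path, experiment_id: str) -> Path:
    return output_dir / f"{experiment_id}{RESULT_SUFFIX}"


def is_complete(path) -> bool:
    """True iff the file parses and its footer digest matches its payload."""
    try:
        text = Path(path).read_text(encoding="utf-8")
        payload, prov = reporting.split_payload(text)
        return prov.get("payload_sha256") == reporting.payload_digest(payload)
    except (OSError, reporting.ResultParseError):
        return False


def commit_result(outcome: ExperimentOutcome, output_dir) -> Path:
    """Atomically write the outcome's result file (temp + rename)."""
    output_dir = Path(output_dir)
    text = render_result(outcome)
    final = _result_path(output_dir, outcome.experiment_id)
    fd, tmp = tempfile.mkstemp(
        prefix=TMP_PREFIX, suffix=RESULT_SUFFIX, dir=output_dir
    )
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
            fh.flush()
            os.fsync(fh.fileno())
        os.replace(tmp, final)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise
    return final


def _write_manifest(output_dir: Path, digest: str, statuses: dict[str, str]) -> None:
    manifest = {
        "spec_sha256": digest,
        "total": len(statuses),
        "status": statuses,
        "updated": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    fd, tmp = tempfile.mkstemp(prefix=TMP_PREFIX, suffix=".json", dir=output_dir)
    with os.fdopen(fd, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    os.replace(tmp, output_dir / MANIFEST_NAME)


def plan_run(
    spec: ExperimentSpec,
    output_dir,
    resume: bool = False,
    force: bool = False,
    retry_failed: bool = True,
) -> tuple[list[ExperimentConfig], list[ExperimentConfig]]:
    """Decide which experiments still need to run.

    Returns (grid, pending).  With ``resume`` the pending set is the grid
    minus experiments whose result file exists, is complete, and — when
    ``retry_failed`` (the default) — did not record a failure; partial or
    corrupt files always re-run.  Without ``resume``, any existing result
    file makes the run refuse unless ``force`` clears them first.
    """
    violations = validate_spec(spec)
    if violations:
        raise SpecValidationError(violations)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    grid = expand(spec)
    digest = spec_digest(spec)

    manifest_path = output_dir / MANIFEST_NAME
    if resume and manifest_path.exists():
        try:
            stored = json.loads(manifest_path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError):
            stored = {}
        stored_digest = stored.get("spec_sha256")
        if stored_digest and stored_digest != digest:
            raise StaleResultsError(
                "output directory holds results for a different specification "
                f"(stored digest {stored_digest[:12]}..., current {digest[:12]}...); "
                "use a fresh directory or re-run without --resume --force"
            )

    existing = {
        cfg.experiment_id: _result_path(output_dir, cfg.experiment_id)
        for cfg in grid
        if _result_path(output_dir, cfg.experiment_id).exists()
    }

    if not resume:
        if existing and not force:
            raise RefusingOverwriteError(
                f"{len(existing)} result file(s) already present in "
                f"{output_dir}; pass --resume to continue or --force to overwrite"
            )
        for path in existing.values():
            path.unlink()
        (output_dir / SUMMARY_NAME).unlink(missing_ok=True)
        pending = list(grid)
    else:
        pending = []
        for cfg in grid:
            path = existing.get(cfg.experiment_id)
            if path is None or not is_complete(path):
                pending.append(cfg)
                continue
            try:
                outcome = parse_result(path.read_text(encoding="utf-8"))
            except reporting.ResultParseError:
                pending.append(cfg)
                continue
            if outcome.status == "failed" and retry_failed:
                pending.append(cfg)

    statuses = {
        cfg.experiment_id: (
            "complete"
            if cfg.experiment_id in existing and cfg not in pending
            else "pending"
        )
        for cfg in grid
    }
    _write_manifest(output_dir, digest, statuses)
    return grid, pending


# -- worker-side ------------------------------------------------------------

_DATASET_CACHE: dict[tuple[str, str], object] = {}


def _load_cached(dataset_ref: str, class_attribute: str):
    key = (dataset_ref, class_attribute)
    if key not in _DATASET_CACHE:
        _DATASET_CACHE.clear()  # keep at most one dataset resident
        _DATASET_CACHE[key] = load_dataset(dataset_ref, class_attribute)
    return _DATASET_CACHE[key]


def _run_one(config: ExperimentConfig, class_attribute: str) -> ExperimentOutcome:
    """Run one experiment; never raises — failures become failed outcomes."""
    start = time.perf_counter()
    try:
        dataset = _load_cached(config.dataset_ref, class_attribute)
        result = evaluate_config(dataset, config, default_registry())
        return ExperimentOutcome(
            config=config,
            status="success",
            result=result,
            duration_s=time.perf_counter() - start,
        )
    except Exception:
        return ExperimentOutcome(
            config=config,
            status="failed",
            error_text=traceback.format_exc(limit=8),
            duration_s=time.perf_counter() - start,
        )


def execute(
    pending: list[ExperimentConfig],
    output_dir,
    workers=1,
    class_attribute: str = "last",
    stop_after: int | None = None,
    log=None,
) -> tuple[list[ExperimentOutcome], bool]:
    """Run pending experiments, committing each result file on completion.

    Returns (outcomes, interrupted).  ``stop_after`` abandons the run
    after that many commits — the fault-injection hook used to exercise
    crash/resume behaviour.  ``log`` is an optional callable receiving
    one structured line per experiment start/finish.
    """
    output_dir = Path(output_dir)
    n_workers = resolve_workers(workers)
    outcomes: list[ExperimentOutcome] = []
    interrupted = False
    log = log or (lambda line: None)

    def commit(outcome: ExperimentOutcome) -> bool:
        commit_result(outcome, output_dir)
        outcomes.append(outcome)
        log(f"finish {outcome.experiment_id} status={outcome.status}")
        return stop_after is not None and len(outcomes) >= stop_after

    if stop_after is not None and stop_after <= 0:
        return [], bool(pending)

    if n_workers == 1 or len(pending) <= 1:
        for cfg in pending:
            log(f"start {cfg.experiment_id}")
            if commit(_run_one(cfg, class_attribute)):
                interrupted = len(outcomes) < len(pending)
                break
        return outcomes, interrupted

    with ProcessPoolExecutor(max_workers=n_workers) as pool:
        futures = {}
        for cfg in pending:
            log(f"start {cfg.experiment_id}")
            futures[pool.submit(_run_one, cfg, class_attribute)] = cfg
        not_done = set(futures)
        while not_done:
            done, not_done = wait(not_done, return_when=FIRST_COMPLETED)
            stop = False
            for fut in done:
                if commit(fut.result()):
                    stop = True
            if stop:
                interrupted = len(outcomes) < len(pending)
                for fut in not_done:
                    fut.cancel()
                break
    return outcomes, interrupted


def run(
    spec: ExperimentSpec,
    output_dir=None,
    workers=None,
    resume: bool = False,
    force: bool = False,
    retry_failed: bool = True,
    stop_after: int | None = None,
    log=None,
) -> RunReport:
    """Plan, execute and summarise a whole specification.

    ``output_dir`` and ``workers`` default to the spec's own settings.
    On normal completion the summary CSV and manifest cover the entire
    grid (including experiments satisfied from existing result files);
    an interrupted run (``stop_after``) skips the summary, exactly as a
    crash would.
    """
    output_dir = Path(output_dir if output_dir is not None else spec.output_dir)
    workers = spec.workers if workers is None else workers
    grid, pending = plan_run(
        spec, output_dir, resume=resume, force=force, retry_failed=retry_failed
    )
    executed, interrupted = execute(
        pending,
        output_dir,
        workers=workers,
        class_attribute=spec.class_attribute,
        stop_after=stop_after,
        log=log,
    )

    if interrupted:
        return RunReport(
            outcomes=executed,
            executed=len(executed),
            skipped=0,
            interrupted=True,
            output_dir=output_dir,
        )

    by_id = {o.experiment_id: o for o in executed}
    outcomes: list[ExperimentOutcome] = []
    skipped = 0
    for cfg in grid:
        o = by_id.get(cfg.experiment_id)
        if o is None:
            path = _result_path(output_dir, cfg.experiment_id)
            o = parse_result(path.read_text(encoding="utf-8"))
            o.config = cfg  # keep grid-order param declaration
            skipped += 1
        outcomes.append(o)

    summary = reporting.write_summary(outcomes, spec)
    fd, tmp = tempfile.mkstemp(prefix=TMP_PREFIX, suffix=".csv", dir=output_dir)
    with os.fdopen(fd, "w", encoding="utf-8") as fh:
        fh.write(summary)
    os.replace(tmp, output_dir / SUMMARY_NAME)

    _write_manifest(
        output_dir,
        spec_digest(spec),
        {o.experiment_id: ("complete" if o.status == "success" else "failed") for o in outcomes},
    )
    return RunReport(
        outcomes=outcomes,
        executed=len(executed),
        skipped=skipped,
        interrupted=False,
        output_dir=output_dir,
    )
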