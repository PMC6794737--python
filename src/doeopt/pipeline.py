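"""Configuration parsing, command rendering, and pipeline execution.

A YAML document declares the factor space, the responses, design options,
and an ordered list of shell command templates with ``{{FACTOR}}``
placeholders.  Each run renders one batch script per step into its own
working directory, executes them in order, and reads responses back from a
small results file (``name: value`` lines, or one bare number in
single-response mode).
"""

from __future__ import annotations

import concurrent.futures
import logging
import math
import re
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .design import CATEGORICAL, Factor, ORDINAL, round_half_up
from .desirability import ResponseSpec
from .errors import ConfigError, RenderError, ValidationError
from .runs import (
    STATUS_FAILED,
    STATUS_INVALID,
    STATUS_OK,
    RunRecord,
)

logger = logging.getLogger(__name__)

PLACEHOLDER_RE = re.compile(r"\{\{\s*([A-Za-z_]\w*)\s*\}\}")


@dataclass
class DesignOptions:
    reduction_factor: int | None = None
    optimization_design: str = "ccf"
    shrinkage: float = 0.9
    step_fraction: float = 0.25
    model_selection: str | None = None
    q2_threshold: float = 0.5
    levels: int = 5
    levels_per_factor: dict = field(default_factory=dict)
    max_iterations: int = 25
    max_restarts: int = 3


@dataclass
class ExecutionOptions:
    mode: str = "sequential"
    workdir: str = "doeopt_work"
    results_file: str = "results.txt"
    scheduler: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    factors: list[Factor]
    responses: list[ResponseSpec]
    design: DesignOptions
    steps: list[tuple[str, str]]  # (name, command template)
    execution: ExecutionOptions

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]


_FACTOR_KEYS = {"type", "min", "max", "categories", "levels"}
_RESPONSE_KEYS = {"criterion", "low_limit", "high_limit", "target"}


def _parse_factor(name: str, spec: Mapping) -> Factor:
    unknown = set(spec) - _FACTOR_KEYS
    if unknown:
        raise ConfigError(f"factor {name!r}: unknown keys {sorted(unknown)}")
    kind = spec.get("type")
    if kind == CATEGORICAL:
        return Factor(
            name,
            CATEGORICAL,
            categories=tuple(str(c) for c in spec.get("categories", ())),
        )
    try:
        return Factor(
            name,
            kind,
            minimum=spec.get("min"),
            maximum=spec.get("max"),
            n_levels=spec.get("levels"),
        )
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _parse_response(name: str, spec: Mapping) -> ResponseSpec:
    unknown = set(spec) - _RESPONSE_KEYS
    if unknown:
        raise ConfigError(f"response {name!r}: unknown keys {sorted(unknown)}")
    try:
        return ResponseSpec(
            name,
            spec.get("criterion", "maximize"),
            low_limit=spec.get("low_limit"),
            high_limit=spec.get("high_limit"),
            target=spec.get("target"),
        )
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(text: str) -> PipelineConfig:
    """Parse and validate a configuration document."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed YAML{where}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration must be a YAML mapping")
    if "design" not in doc or "pipeline" not in doc:
        raise ConfigError("configuration needs 'design' and 'pipeline' sections")

    dsec = doc["design"]
    fsec = dsec.get("factors")
    rsec = dsec.get("responses")
    if not fsec:
        raise ConfigError("design.factors must declare at least one factor")
    if not rsec:
        raise ConfigError("design.responses must declare at least one response")
    factors = [_parse_factor(str(n), s or {}) for n, s in fsec.items()]
    responses = [_parse_response(str(n), s or {}) for n, s in rsec.items()]
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ConfigError("factor names must be unique")
    if len({r.name for r in responses}) != len(responses):
        raise ConfigError("response names must be unique")
    if len(responses) > 1:
        for r in responses:
            try:
                r.validate_for_desirability()
            except ValidationError as exc:
                raise ConfigError(
                    f"multi-response mode: {exc}"
                ) from exc

    options = DesignOptions(
        reduction_factor=dsec.get("reduction_factor"),
        optimization_design=dsec.get("optimization_design", "ccf"),
        shrinkage=float(dsec.get("shrinkage", 0.9)),
        step_fraction=float(dsec.get("step_fraction", 0.25)),
        model_selection=dsec.get("model_selection"),
        q2_threshold=float(dsec.get("q2_threshold", 0.5)),
        levels=int(dsec.get("levels", 5)),
        levels_per_factor={
            f.name: f.n_levels for f in factors if f.n_levels is not None
        },
        max_iterations=int(dsec.get("max_iterations", 25)),
        max_restarts=int(dsec.get("max_restarts", 3)),
    )
    if options.optimization_design != "ccf":
        raise ConfigError(
            f"unsupported optimization design {options.optimization_design!r}"
        )
    if options.model_selection not in (None, "best_subset", "greedy", "greedy_forward"):
        raise ConfigError(
            f"unknown model_selection {options.model_selection!r}"
        )
    if options.model_selection == "greedy":
        options.model_selection = "greedy_forward"

    psec = doc["pipeline"]
    if isinstance(psec, Mapping):
        steps = [(str(n), str(cmd)) for n, cmd in psec.items()]
    else:
        steps = [(str(s["name"]), str(s["command"])) for s in psec]
    if not steps:
        raise ConfigError("pipeline must declare at least one step")
    declared = set(names)
    for step_name, template in steps:
        for ph in PLACEHOLDER_RE.findall(template):
            if ph not in declared:
                raise ConfigError(
                    f"step {step_name!r}: placeholder {{{{{ph}}}}} does not "
                    "name a declared factor"
                )

    esec = doc.get("execution", {}) or {}
    execution = ExecutionOptions(
        mode=esec.get("mode", "sequential"),
        workdir=str(esec.get("workdir", "doeopt_work")),
        results_file=str(esec.get("results_file", "results.txt")),
        scheduler=dict(esec.get("scheduler", {}) or {}),
    )
    if execution.mode not in ("sequential", "parallel"):
        raise ConfigError(f"unknown execution mode {execution.mode!r}")
    return PipelineConfig(factors, responses, options, steps, execution)


def serialize(config: PipelineConfig) -> str:
    """Inverse of :func:`load_config` for the fixture round-trip contract."""
    fsec = {}
    for f in config.factors:
        if f.kind == CATEGORICAL:
            fsec[f.name] = {"type": f.kind, "categories": list(f.categories)}
        else:
            fsec[f.name] = {"type": f.kind, "min": f.minimum, "max": f.maximum}
            if f.n_levels is not None:
                fsec[f.name]["levels"] = f.n_levels
    rsec = {}
    for r in config.responses:
        entry: dict = {"criterion": r.criterion}
        if r.low_limit is not None:
            entry["low_limit"] = r.low_limit
        if r.high_limit is not None:
            entry["high_limit"] = r.high_limit
        if r.target is not None:
            entry["target"] = r.target
        rsec[r.name] = entry
    doc = {
        "design": {
            "factors": fsec,
            "responses": rsec,
            "optimization_design": config.design.optimization_design,
            "shrinkage": config.design.shrinkage,
            "step_fraction": config.design.step_fraction,
            "q2_threshold": config.design.q2_threshold,
            "levels": config.design.levels,
            "max_iterations": config.design.max_iterations,
            "max_restarts": config.design.max_restarts,
        },
        "pipeline": {name: cmd for name, cmd in config.steps},
        "execution": {
            "mode": config.execution.mode,
            "workdir": config.execution.workdir,
            "results_file": config.execution.results_file,
            "scheduler": config.execution.scheduler,
        },
    }
    if config.design.reduction_factor is not None:
        doc["design"]["reduction_factor"] = config.design.reduction_factor
    if config.design.model_selection is not None:
        doc["design"]["model_selection"] = config.design.model_selection
    return yaml.safe_dump(doc, sort_keys=False)


def format_value(factor: Factor, value) -> str:
    """Render one factor value for command substitution."""
    if factor.kind == CATEGORICAL:
        return str(value)
    if factor.kind == ORDINAL:
        return str(round_half_up(float(value)) if not isinstance(value, int) else value)
    return repr(float(value))


def render_run(
    config: PipelineConfig,
    run_id: str,
    configuration: Mapping,
    phase: str = "adhoc",
    root: Path | None = None,
) -> RunRecord:
    """Render (but do not execute) the batch scripts for one run."""
    by_name = {f.name: f for f in config.factors}
    missing = [f for f in by_name if f not in configuration]
    if missing:
        raise RenderError(f"run {run_id}: configuration missing {missing}")
    root = Path(root) if root is not None else Path(config.execution.workdir)
    rundir = root / phase / run_id
    rundir.mkdir(parents=True, exist_ok=True)

    headers = [
        f"#SBATCH --{key}={value}"
        for key, value in config.execution.scheduler.items()
    ]
    scripts = []
    for i, (step_name, template) in enumerate(config.steps):
        def substitute(match: re.Match) -> str:
            name = match.group(1)
            if name not in by_name:
                raise RenderError(
                    f"run {run_id}, step {step_name!r}: unknown placeholder "
                    f"{{{{{name}}}}}"
                )
            return format_value(by_name[name], configuration[name])

        command = PLACEHOLDER_RE.sub(substitute, template)
        if PLACEHOLDER_RE.search(command):
            raise RenderError(
                f"run {run_id}, step {step_name!r}: unsubstituted placeholder"
            )
        script = rundir / f"step_{i:02d}_{step_name}.sh"
        lines = ["#!/bin/bash", *headers, "set -o pipefail", command, ""]
        script.write_text("\n".join(lines))
        script.chmod(0o755)
        scripts.append(str(script))
    return RunRecord(
        run_id=run_id,
        phase=phase,
        configuration=dict(configuration),
        status="pending",
        scripts=scripts,
        workdir=str(rundir),
    )


def parse_results_file(path: Path, single_response: str | None = None) -> dict:
    """Read ``name: value`` lines (or one bare number in single-response mode)."""
    text = path.read_text()
    responses: dict[str, float] = {}
    bare: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line:
            name, _, val = line.partition(":")
            try:
                responses[name.strip()] = float(val.strip())
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: cannot parse value {val.strip()!r}"
                ) from exc
        else:
            try:
                bare.append(float(line))
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 'name: value' or a number"
                ) from exc
    if bare:
        if single_response is None or responses or len(bare) > 1:
            raise ValidationError(
                f"{path}: bare numbers are only allowed alone, in "
                "single-response mode"
            )
        responses[single_response] = bare[0]
    return responses


def _execute_one(record: RunRecord, config: PipelineConfig) -> RunRecord:
    rundir = Path(record.workdir)
    for script in record.scripts:
        proc = subprocess.run(
            ["bash", script],
            cwd=rundir,
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            record.status = STATUS_FAILED
            record.note = (
                f"step {Path(script).name} exited {proc.returncode}: "
                + proc.stderr.strip()[-500:]
            )
            logger.warning("run %s failed: %s", record.run_id, record.note)
            return record
    results_path = rundir / config.execution.results_file
    single = config.responses[0].name if len(config.responses) == 1 else None
    try:
        responses = parse_results_file(results_path, single_response=single)
    except (OSError, ValidationError) as exc:
        record.status = STATUS_INVALID
        record.note = f"results unreadable: {exc}"
        logger.warning("run %s invalid: %s", record.run_id, record.note)
        return record
    missing = [r.name for r in config.responses if r.name not in responses]
    nonfinite = [
        r.name
        for r in config.responses
        if r.name in responses and not math.isfinite(responses[r.name])
    ]
    record.responses = responses
    if missing or nonfinite:
        record.status = STATUS_INVALID
        record.note = f"missing={missing} nonfinite={nonfinite}"
        logger.warning("run %s invalid: %s", record.run_id, record.note)
    else:
        record.status = STATUS_OK
    return record


def execute_and_collect(
    config: PipelineConfig,
    records: Sequence[RunRecord],
    mode: str | None = None,
) -> list[RunRecord]:
    """Execute rendered runs and parse their results files.

    ``parallel`` mode runs whole pipelines concurrently (thread pool over
    subprocesses); within one run the steps are always sequential.  For
    deterministic pipelines both modes yield identical records.
    """
    mode = mode or config.execution.mode
    if mode == "sequential":
        return [_execute_one(r, config) for r in records]
    if mode != "parallel":
        raise ValidationError(f"unknown execution mode {mode!r}")
    with concurrent.futures.ThreadPoolExecutor(max_workers=8) as pool:
        futures = [pool.submit(_execute_one, r, config) for r in records]
        return [f.result() for f in futures]


class PipelineExecutor:
    """Executor backed by real subprocess execution of the configured steps."""

    def __init__(self, config: PipelineConfig, root: Path | None = None):
        self.config = config
        self.root = Path(root) if root is not None else Path(config.execution.workdir)
        self._counter = 0
        self.records: list[RunRecord] = []

    def run(self, phase: str, configurations: Sequence[Mapping]) -> list[RunRecord]:
        records = []
        for cfg in configurations:
            self._counter += 1
            run_id = f"r{self._counter:05d}"
            records.append(
                render_run(self.config, run_id, cfg, phase=phase, root=self.root)
            )
        executed = execute_and_collect(self.config, records)
        self.records.extend(executed)
        return executed


def percent_improvement(
    default_value: float, optimized_value: float, criterion: str
) -> float:
    """Percent improvement of optimized over default, half-up to one decimal."""
    if default_value == 0:
        raise ValidationError("percent improvement undefined for default = 0")
    if criterion == "maximize":
        pct = (optimized_value - default_value) / default_value * 100.0
    elif criterion == "minimize":
        pct = (default_value - optimized_value) / default_value * 100.0
    else:
        raise ValidationError(f"criterion must be maximize or minimize ({criterion!r})")
    return math.floor(pct * 10 + 0.5) / 10.0
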