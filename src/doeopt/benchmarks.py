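"""Seeded mock objectives and a mock pipeline CLI.

These stand in for real bioinformatics tools so the whole optimizer is
testable end-to-end with no external data: quadratic surfaces with known
optima, optional factor interactions, per-category offsets, and
deterministic per-configuration noise.  Also hosts the grid-search baseline
and the F1 helper.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
import math
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import design as dz
from .desirability import ResponseSpec, ScoredRun, rank_runs
from .errors import ValidationError
from .runs import RunRecord, STATUS_FAILED, STATUS_OK

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MockObjective:
    """Concave quadratic surface with a known global maximum.

    ``y = y0 - sum_f curvature_f (x_f - opt_f)^2
           + sum_{f<g} weight_fg (x_f - opt_f)(x_g - opt_g)
           + offset(category) + noise``

    Multi-response objectives emit one response per entry of
    ``response_shifts``; each response's optima are the base optima plus its
    per-factor shift, so responses can conflict.
    """

    optima: Mapping[str, float]
    curvatures: Mapping[str, float]
    interactions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    categorical_offsets: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    y0: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    response_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"y": {}}
    )

    def __post_init__(self) -> None:
        names = sorted(self.optima)
        if set(self.curvatures) != set(names):
            raise ValidationError("curvatures must cover exactly the optima factors")
        if any(c <= 0 for c in self.curvatures.values()):
            raise ValidationError("curvatures must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for pair in self.interactions:
            if len(pair) != 2 or any(f not in self.optima for f in pair):
                raise ValidationError(f"bad interaction pair {pair!r}")
        # the quadratic form must be negative definite, otherwise the
        # declared optima are not the global maximum
        k = len(names)
        if k and self.interactions:
            hess = np.zeros((k, k))
            pos = {f: i for i, f in enumerate(names)}
            for f in names:
                hess[pos[f], pos[f]] = -2.0 * self.curvatures[f]
            # cross-partial of w*(xf-of)(xg-og) is w
            for (f, g), w in self.interactions.items():
                hess[pos[f], pos[g]] += w
                hess[pos[g], pos[f]] += w
            if np.linalg.eigvalsh(hess).max() >= 0:
                raise ValidationError(
                    "interaction weights break concavity: optima would not be "
                    "the global maximum"
                )

    @property
    def factor_names(self) -> list[str]:
        names = sorted(self.optima)
        names += sorted({f for f, _ in self.categorical_offsets if f not in names})
        return names

    @property
    def response_names(self) -> list[str]:
        return list(self.response_shifts)

    def best_categories(self) -> dict[str, str]:
        best: dict[str, tuple[str, float]] = {}
        for (factor, category), offset in self.categorical_offsets.items():
            if factor not in best or offset > best[factor][1]:
                best[factor] = (category, offset)
        return {f: c for f, (c, _) in best.items()}

    def _noise(self, response: str, configuration: Mapping) -> float:
        if self.noise_sd == 0.0:
            return 0.0
        payload = json.dumps(
            [self.seed, response, sorted(configuration.items())],
            sort_keys=True,
            default=str,
        )
        digest = hashlib.sha256(payload.encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return float(rng.normal(0.0, self.noise_sd))

    def evaluate(self, configuration: Mapping) -> dict[str, float]:
        """Deterministic response values for one configuration."""
        for f in self.factor_names:
            if f not in configuration:
                raise ValidationError(f"configuration missing factor {f!r}")
        unknown = set(configuration) - set(self.factor_names)
        if unknown:
            raise ValidationError(f"unknown factors {sorted(unknown)}")
        out: dict[str, float] = {}
        for response, shifts in self.response_shifts.items():
            y = self.y0
            delta = {
                f: float(configuration[f]) - (self.optima[f] + shifts.get(f, 0.0))
                for f in self.optima
            }
            for f, d in delta.items():
                y -= self.curvatures[f] * d * d
            for (f, g), w in self.interactions.items():
                y += w * delta[f] * delta[g]
            for (factor, category), offset in self.categorical_offsets.items():
                if str(configuration.get(factor)) == category:
                    y += offset
            out[response] = y + self._noise(response, configuration)
        return out

    def to_dict(self) -> dict:
        return {
            "optima": dict(self.optima),
            "curvatures": dict(self.curvatures),
            "interactions": [
                {"factors": list(pair), "weight": w}
                for pair, w in self.interactions.items()
            ],
            "categorical_offsets": [
                {"factor": f, "category": c, "offset": o}
                for (f, c), o in self.categorical_offsets.items()
            ],
            "y0": self.y0,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "response_shifts": {
                r: dict(s) for r, s in self.response_shifts.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MockObjective":
        return cls(
            optima=dict(doc["optima"]),
            curvatures=dict(doc["curvatures"]),
            interactions={
                tuple(e["factors"]): float(e["weight"])
                for e in doc.get("interactions", [])
            },
            categorical_offsets={
                (e["factor"], e["category"]): float(e["offset"])
                for e in doc.get("categorical_offsets", [])
            },
            y0=float(doc.get("y0", 0.0)),
            noise_sd=float(doc.get("noise_sd", 0.0)),
            seed=int(doc.get("seed", 0)),
            response_shifts=doc.get("response_shifts", {"y": {}}),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "MockObjective":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def evaluate(objective: MockObjective, configuration: Mapping) -> dict[str, float]:
    """Functional alias for :meth:`MockObjective.evaluate`."""
    return objective.evaluate(configuration)


class MockExecutor:
    """In-process executor evaluating a :class:`MockObjective` directly."""

    def __init__(self, objective: MockObjective, fail_predicate=None):
        self.objective = objective
        self.fail_predicate = fail_predicate
        self._counter = 0
        self.records: list[RunRecord] = []

    def run(self, phase: str, configurations: Sequence[Mapping]) -> list[RunRecord]:
        out = []
        for cfg in configurations:
            self._counter += 1
            rec = RunRecord(
                run_id=f"r{self._counter:05d}",
                phase=phase,
                configuration=dict(cfg),
            )
            if self.fail_predicate is not None and self.fail_predicate(cfg):
                rec.status = STATUS_FAILED
                rec.note = "fail predicate matched"
            else:
                rec.responses = self.objective.evaluate(cfg)
                rec.status = STATUS_OK
            out.append(rec)
            self.records.append(rec)
        return out


def grid_search(
    factors: Sequence[dz.Factor],
    specs: Sequence[ResponseSpec],
    executor,
    levels: Mapping[str, int] | int | None = None,
) -> tuple[dict, ScoredRun, int]:
    """Exhaustive baseline: full factorial at the screening resolution.

    Returns (best configuration, best scored run, executed run count).
    """
    factors = list(factors)
    if not factors:
        raise ValidationError("grid search needs at least one factor")

    def n_for(fac: dz.Factor):
        if isinstance(levels, int):
            return levels
        if isinstance(levels, Mapping):
            return levels.get(fac.name)
        return None

    lvls = {f.name: dz.screening_levels(f, n_for(f)) for f in factors}
    names = [f.name for f in factors]
    ffd = dz.generate_full_factorial([len(lvls[n]) for n in names], names=names)
    concrete = dz.decode_design(ffd, lvls)
    records = executor.run("gridsearch", list(concrete.rows))
    scored = rank_runs(
        {r.run_id: (r.responses if r.status == STATUS_OK else None) for r in records},
        specs,
    )
    best = scored[0]
    if not best.valid:
        raise ValidationError("grid search produced no valid runs")
    best_config = next(
        dict(r.configuration) for r in records if r.run_id == best.run_id
    )
    return best_config, best, len(records)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1] (got {v})")
    if precision == 0.0 and recall == 0.0:
        logger.warning("f1_score(0, 0): harmonic mean degenerate, returning 0")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


_PREDICATE_RE = re.compile(
    r"^\s*([A-Za-z_]\w*)\s*(<=|>=|==|!=|<|>)\s*(-?\d+(?:\.\d+)?)\s*$"
)

_OPS = {
    "<": lambda a, b: a < b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def parse_fail_predicate(expr: str):
    """Compile a tiny '<factor> <op> <number>' predicate for error-path tests."""
    m = _PREDICATE_RE.match(expr)
    if m is None:
        raise ValidationError(f"cannot parse predicate {expr!r}")
    name, op, number = m.group(1), m.group(2), float(m.group(3))
    return lambda cfg: name in cfg and _OPS[op](float(cfg[name]), number)


def _parse_setting(text: str):
    if "=" not in text:
        raise ValidationError(f"--set expects NAME=VALUE (got {text!r})")
    name, _, raw = text.partition("=")
    for cast in (int, float):
        try:
            return name, cast(raw)
        except ValueError:
            continue
    return name, raw


def mock_pipeline_cli(argv: Sequence[str] | None = None) -> int:
    """Console entry point ``doeopt-mock``: evaluate a mock objective spec
    and write a results file consumable by the pipeline runner."""
    parser = argparse.ArgumentParser(
        prog="doeopt-mock",
        description="Evaluate a mock objective and write 'name: value' lines.",
    )
    parser.add_argument("--spec", required=True, help="objective spec (YAML)")
    parser.add_argument("--out", default="results.txt", help="results file path")
    parser.add_argument(
        "--set",
        dest="settings",
        action="append",
        default=[],
        metavar="NAME=VALUE",
        help="factor setting (repeatable)",
    )
    parser.add_argument(
        "--fail-if",
        default=None,
        metavar="EXPR",
        help="exit 1 when '<factor> <op> <number>' holds (error-path testing)",
    )
    try:
        args = parser.parse_args(argv)
        objective = MockObjective.load(args.spec)
        configuration = dict(_parse_setting(s) for s in args.settings)
        if args.fail_if is not None and parse_fail_predicate(args.fail_if)(
            configuration
        ):
            print(f"doeopt-mock: fail predicate {args.fail_if!r} matched",
                  file=sys.stderr)
            return 1
        responses = objective.evaluate(configuration)
    except (ValidationError, OSError, yaml.YAMLError, KeyError) as exc:
        print(f"doeopt-mock: error: {exc}", file=sys.stderr)
        return 2
    lines = [f"{name}: {value!r}" for name, value in responses.items()]
    Path(args.out).write_text("\n".join(lines) + "\n")
    return 0


def main() -> None:  # pragma: no cover - console-script shim
    sys.exit(mock_pipeline_cli())


def random_objective(
    rng: np.random.Generator,
    factors: Sequence[dz.Factor],
    *,
    margin: float = 0.15,
    noise_sd: float = 0.0,
    with_interactions: bool = True,
) -> MockObjective:
    """Draw a random concave quadratic mock over the given numeric factors.

    Optima are placed in the interior (at least ``margin`` of the range away
    from each bound); interaction weights are kept small enough to preserve
    concavity.
    """
    numeric = [f for f in factors if f.is_numeric]
    optima = {}
    curvatures = {}
    for f in numeric:
        lo = f.minimum + margin * f.span
        hi = f.maximum - margin * f.span
        opt = float(rng.uniform(lo, hi))
        if f.kind == dz.ORDINAL:
            opt = float(dz.round_half_up(opt))
        optima[f.name] = opt
        # curvature scaled so the response varies O(1) over the range
        curvatures[f.name] = float(rng.uniform(0.5, 2.0)) / f.span**2
    interactions = {}
    if with_interactions and len(numeric) >= 2:
        names = sorted(optima)
        for i in range(len(names) - 1):
            f, g = names[i], names[i + 1]
            # |w| < 0.7*sqrt(cf*cg) keeps the Hessian diagonally dominant
            # (curvature ratios are bounded by 4 by construction)
            bound = math.sqrt(curvatures[f] * curvatures[g])
            interactions[(f, g)] = float(rng.uniform(-0.35, 0.35)) * bound
    return MockObjective(
        optima=optima,
        curvatures=curvatures,
        interactions=interactions,
        y0=1.0,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
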