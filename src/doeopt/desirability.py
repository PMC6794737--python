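"""Derringer–Suich desirability scoring and run ranking.

Each response is rescaled to [0, 1] with linear ramps: 0 at/outside the
failing limit, 1 at/beyond the target.  Multiple responses are combined into
one overall score with the geometric mean.  Single-response optimizations
bypass desirability entirely and are compared on the raw value under the
declared criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ScoringError, ValidationError

logger = logging.getLogger(__name__)

MAXIMIZE = "maximize"
MINIMIZE = "minimize"
TARGET = "target"
CRITERIA = (MAXIMIZE, MINIMIZE, TARGET)


@dataclass(frozen=True)
class ResponseSpec:
    """Declaration of one measured response and its acceptability window."""

    name: str
    criterion: str
    low_limit: float | None = None
    high_limit: float | None = None
    target: float | None = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValidationError(
                f"response {self.name!r}: unknown criterion {self.criterion!r}"
            )
        # Limit consistency is checked for whatever was declared; whether a
        # target/limit is required at all depends on single- vs multi-response
        # mode and is enforced by validate_for_desirability / config loading.
        if self.criterion == MAXIMIZE:
            if (
                self.low_limit is not None
                and self.target is not None
                and not (self.low_limit < self.target)
            ):
                raise ValidationError(
                    f"response {self.name!r}: maximize needs low_limit < target"
                )
        elif self.criterion == MINIMIZE:
            if (
                self.high_limit is not None
                and self.target is not None
                and not (self.target < self.high_limit)
            ):
                raise ValidationError(
                    f"response {self.name!r}: minimize needs target < high_limit"
                )
        else:  # target
            if None not in (self.low_limit, self.target, self.high_limit):
                if not (self.low_limit < self.target < self.high_limit):
                    raise ValidationError(
                        f"response {self.name!r}: target criterion needs "
                        "low_limit < target < high_limit"
                    )

    @property
    def scorable(self) -> bool:
        """True when limits/target suffice to compute a desirability."""
        if self.criterion == MAXIMIZE:
            return self.low_limit is not None and self.target is not None
        if self.criterion == MINIMIZE:
            return self.high_limit is not None and self.target is not None
        return None not in (self.low_limit, self.target, self.high_limit)

    def validate_for_desirability(self) -> None:
        if not self.scorable:
            raise ValidationError(
                f"response {self.name!r}: criterion {self.criterion!r} needs "
                "limits and target for desirability scoring"
            )


def desirability_score(value: float, spec: ResponseSpec) -> float:
    """Rescale one response value to [0, 1] under ``spec``.

    Values at or beyond the failing limit score exactly 0; values at or
    beyond the target score exactly 1; linear in between.
    """
    if value is None or not math.isfinite(value):
        raise ScoringError(
            f"response {spec.name!r}: non-finite value {value!r}"
        )
    spec.validate_for_desirability()
    if spec.criterion == MAXIMIZE:
        if value <= spec.low_limit:
            return 0.0
        if value >= spec.target:
            return 1.0
        return (value - spec.low_limit) / (spec.target - spec.low_limit)
    if spec.criterion == MINIMIZE:
        if value >= spec.high_limit:
            return 0.0
        if value <= spec.target:
            return 1.0
        return (spec.high_limit - value) / (spec.high_limit - spec.target)
    # two-sided tent, 1 at target, 0 at/outside both limits
    if value <= spec.low_limit or value >= spec.high_limit:
        return 0.0
    if value == spec.target:
        return 1.0
    if value < spec.target:
        return (value - spec.low_limit) / (spec.target - spec.low_limit)
    return (spec.high_limit - value) / (spec.high_limit - spec.target)


def desirability_array(values: np.ndarray, spec: ResponseSpec) -> np.ndarray:
    """Vectorized :func:`desirability_score` over an array of values."""
    spec.validate_for_desirability()
    v = np.asarray(values, dtype=float)
    if spec.criterion == MAXIMIZE:
        d = (v - spec.low_limit) / (spec.target - spec.low_limit)
    elif spec.criterion == MINIMIZE:
        d = (spec.high_limit - v) / (spec.high_limit - spec.target)
    else:
        up = (v - spec.low_limit) / (spec.target - spec.low_limit)
        down = (spec.high_limit - v) / (spec.high_limit - spec.target)
        d = np.minimum(up, down)
    return np.clip(d, 0.0, 1.0)


def overall_desirability(desirabilities: Sequence[float]) -> float:
    """Geometric mean of per-response desirabilities; 0 annihilates."""
    ds = list(desirabilities)
    if not ds:
        raise ValidationError("overall_desirability needs >= 1 desirability")
    for d in ds:
        if not (0.0 <= d <= 1.0):
            raise ValidationError(f"desirability {d} outside [0, 1]")
    if any(d == 0.0 for d in ds):
        return 0.0
    return float(math.exp(sum(math.log(d) for d in ds) / len(ds)))


@dataclass(frozen=True)
class ScoredRun:
    """One executed run with its raw responses and desirability scores."""

    run_id: str
    responses: Mapping[str, float]
    desirabilities: Mapping[str, float] = field(default_factory=dict)
    overall: float = float("nan")
    valid: bool = True
    note: str = ""


def _raw_key(value: float, spec: ResponseSpec) -> float:
    """Sort key (higher = better) for single-response raw comparison."""
    if spec.criterion == MAXIMIZE:
        return value
    if spec.criterion == MINIMIZE:
        return -value
    if spec.target is None:
        raise ValidationError(
            f"response {spec.name!r}: target criterion needs a target"
        )
    return -abs(value - spec.target)


def ranking_key(run: ScoredRun, specs: Sequence[ResponseSpec]) -> float:
    """Comparable quality of a scored run: higher is better."""
    if not run.valid:
        return -math.inf
    if len(specs) == 1:
        return _raw_key(run.overall, specs[0])
    return run.overall


def score_run(
    run_id: str,
    responses: Mapping[str, float] | None,
    specs: Sequence[ResponseSpec],
) -> ScoredRun:
    """Score one run; missing or non-finite responses mark it invalid."""
    responses = dict(responses or {})
    missing = [s.name for s in specs if s.name not in responses]
    nonfinite = [
        s.name
        for s in specs
        if s.name in responses
        and (
            responses[s.name] is None
            or not math.isfinite(float(responses[s.name]))
        )
    ]
    if missing or nonfinite:
        note = []
        if missing:
            note.append(f"missing responses: {missing}")
        if nonfinite:
            note.append(f"non-finite responses: {nonfinite}")
        logger.warning("run %s invalid (%s)", run_id, "; ".join(note))
        return ScoredRun(run_id, responses, {}, float("nan"), False, "; ".join(note))
    if len(specs) == 1:
        # single-response mode: overall carries the raw value
        return ScoredRun(
            run_id, responses, {}, float(responses[specs[0].name]), True, ""
        )
    des = {s.name: desirability_score(float(responses[s.name]), s) for s in specs}
    return ScoredRun(
        run_id, responses, des, overall_desirability(list(des.values())), True, ""
    )


def rank_runs(
    runs: Mapping[str, Mapping[str, float] | None],
    specs: Sequence[ResponseSpec],
) -> list[ScoredRun]:
    """Score and order runs, best first.

    Valid runs are ordered by descending quality (overall desirability, or
    the raw value under the criterion in single-response mode); ties break
    toward the lowest run id.  Invalid runs sort last, flagged.
    """
    if not specs:
        raise ValidationError("rank_runs needs >= 1 response spec")
    scored = [score_run(rid, resp, specs) for rid, resp in runs.items()]
    valid = [s for s in scored if s.valid]
    invalid = [s for s in scored if not s.valid]
    valid.sort(key=lambda s: (-ranking_key(s, specs), s.run_id))
    invalid.sort(key=lambda s: s.run_id)
    return valid + invalid
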