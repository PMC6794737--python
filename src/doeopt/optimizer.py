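"""Two-phase optimization controller.

Phase 1 screens the full factor space with a generalized subset design and
fixes categorical factors at the best configuration found.  Phase 2 runs
central composite face-centered designs around the current center, fits OLS
surrogates, executes a validation run at the predicted optimum when the
model's Q2 clears the threshold, and moves/shrinks the design region until
convergence.  If the best result never reaches the acceptable response
limits, optimization restarts from the next-best screening configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import design as dz
from . import surrogate as sm
from .desirability import (
    ResponseSpec,
    ScoredRun,
    desirability_score,
    rank_runs,
    ranking_key,
)
from .errors import (
    IterationError,
    ScreeningError,
    SelectionError,
    ValidationError,
)
from .runs import AuditTrail, Executor, RunRecord

logger = logging.getLogger(__name__)

DEFAULT_SHRINKAGE = 0.9
DEFAULT_STEP_FRACTION = 0.25
DEFAULT_Q2_THRESHOLD = 0.5
DEFAULT_MAX_ITERATIONS = 25
DEFAULT_MAX_RESTARTS = 3


@dataclass
class FactorRegion:
    """Current search interval of one numeric factor: center +/- span/2."""

    center: float
    span: float
    frozen: bool = False

    @property
    def low(self) -> float:
        return self.center - self.span / 2.0

    @property
    def high(self) -> float:
        return self.center + self.span / 2.0


@dataclass
class IterationRecord:
    iteration: int
    runs: list[ScoredRun]
    models: dict | None
    moved: bool
    best: ScoredRun
    best_config: dict


@dataclass
class OptimizationState:
    factors: dict[str, dz.Factor]
    specs: list[ResponseSpec]
    regions: dict[str, FactorRegion]
    fixed: dict[str, object]
    iteration: int = 0
    history: list[IterationRecord] = field(default_factory=list)
    best: ScoredRun | None = None
    best_config: dict | None = None
    shrinkage: float = DEFAULT_SHRINKAGE
    step_fraction: float = DEFAULT_STEP_FRACTION
    q2_threshold: float = DEFAULT_Q2_THRESHOLD
    model_selection: str | None = None
    n_grid: int = 51

    @property
    def active_factors(self) -> list[str]:
        return [f for f, r in self.regions.items() if not r.frozen]

    def region_bounds(self) -> dict[str, tuple[float, float]]:
        out = {}
        for f in self.active_factors:
            r = self.regions[f]
            fac = self.factors[f]
            out[f] = (max(r.low, fac.minimum), min(r.high, fac.maximum))
        return out

    def ordinal_factors(self) -> set[str]:
        return {
            f for f in self.regions if self.factors[f].kind == dz.ORDINAL
        }

    def assert_containment(self) -> None:
        for f, r in self.regions.items():
            fac = self.factors[f]
            if r.low < fac.minimum - 1e-9 or r.high > fac.maximum + 1e-9:
                raise ValidationError(
                    f"factor {f!r}: region [{r.low}, {r.high}] escaped global "
                    f"bounds [{fac.minimum}, {fac.maximum}]"
                )


@dataclass
class ScreeningResult:
    scored: list[ScoredRun]
    records: dict[str, RunRecord]
    levels: dict[str, dz.ScreeningLevels]
    best: ScoredRun
    best_config: dict
    fixed_categoricals: dict


def _clamp(value, factor: dz.Factor):
    v = min(max(value, factor.minimum), factor.maximum)
    if factor.kind == dz.ORDINAL:
        v = dz.round_half_up(v)
    return v


def _score_records(records: Sequence[RunRecord], specs) -> list[ScoredRun]:
    by_id = {
        r.run_id: (r.responses if r.status == "ok" else None) for r in records
    }
    return rank_runs(by_id, specs)


def run_screening(
    factors: Sequence[dz.Factor],
    specs: Sequence[ResponseSpec],
    executor: Executor,
    reduction: int | None = None,
    levels: Mapping[str, int] | int | None = None,
    complementary_index: int = 0,
    audit: AuditTrail | None = None,
) -> ScreeningResult:
    """GSD screening over the full factor space.

    The reduction factor defaults to the number of factors.  Categorical
    factors enter the design with their categories as levels and are fixed
    afterwards at the best run's categories.
    """
    factors = list(factors)
    if not factors:
        raise ValidationError("screening needs at least one factor")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValidationError("factor names must be unique")
    if reduction is None:
        reduction = max(2, len(factors))

    def levels_for(fac: dz.Factor) -> dz.ScreeningLevels:
        n = None
        if isinstance(levels, int):
            n = levels
        elif isinstance(levels, Mapping):
            n = levels.get(fac.name)
        return screening_levels_of(fac, n)

    lvls = {f.name: levels_for(f) for f in factors}
    counts = [len(lvls[n]) for n in names]
    gsd = dz.generate_gsd(counts, reduction, complementary_index, names=names)
    concrete = dz.decode_design(gsd, lvls)
    records = executor.run("screening", list(concrete.rows))
    scored = _score_records(records, specs)
    if audit is not None:
        for rec in records:
            audit.add(rec)
        audit.attach_scores(scored)
    if not any(s.valid for s in scored):
        raise ScreeningError(
            f"all {len(records)} screening runs failed or were invalid"
        )
    best = scored[0]
    rec_by_id = {r.run_id: r for r in records}
    best_config = dict(rec_by_id[best.run_id].configuration)
    fixed_categoricals = {
        f.name: best_config[f.name]
        for f in factors
        if f.kind == dz.CATEGORICAL
    }
    return ScreeningResult(scored, rec_by_id, lvls, best, best_config, fixed_categoricals)


def screening_levels_of(factor: dz.Factor, n: int | None) -> dz.ScreeningLevels:
    return dz.screening_levels(factor, n)


def anchor_interval(values: Sequence[float], best: float) -> tuple[float, float, float]:
    """Midpoint anchoring rule for one factor.

    Returns (center, low, high): center is the screening level nearest to
    ``best``, shifted one level inward when it is the first or last level;
    low/high are the midpoints toward the adjacent levels.
    """
    vals = list(values)
    if len(vals) < 3:
        raise ValidationError(
            "anchoring needs >= 3 screening levels (midpoints undefined)"
        )
    idx = min(range(len(vals)), key=lambda i: (abs(vals[i] - best), i))
    idx = max(1, min(idx, len(vals) - 2))
    center = float(vals[idx])
    low = (center + float(vals[idx - 1])) / 2.0
    high = (center + float(vals[idx + 1])) / 2.0
    return center, low, high


def initialize_rsm(
    best_config: Mapping[str, float],
    levels: Mapping[str, dz.ScreeningLevels],
    factors: Sequence[dz.Factor],
) -> dict[str, FactorRegion]:
    """Anchor the first response-surface region around the screening best."""
    regions: dict[str, FactorRegion] = {}
    for fac in factors:
        if not fac.is_numeric:
            continue
        center, low, high = anchor_interval(
            levels[fac.name].values, float(best_config[fac.name])
        )
        span = high - low
        region = FactorRegion(center=center, span=span)
        # keep center +/- span/2 inside global bounds (uneven rounded levels
        # can push the symmetric region slightly past an edge)
        if region.low < fac.minimum:
            region.center += fac.minimum - region.low
        if region.high > fac.maximum:
            region.center -= region.high - fac.maximum
        regions[fac.name] = region
    return regions


def run_iteration(
    state: OptimizationState,
    executor: Executor,
    audit: AuditTrail | None = None,
) -> IterationRecord:
    """One optimization iteration: CCF runs, model, optional validation run."""
    active = state.active_factors
    if not active:
        raise ValidationError("no active numeric factors to optimize")
    state.iteration += 1
    k = state.iteration

    ccf = dz.generate_ccf(len(active), names=active)
    context = {
        f: (state.regions[f].center, state.regions[f].span) for f in active
    }
    concrete = dz.decode_design(
        ccf, context, ordinal_factors=state.ordinal_factors()
    )
    configs = []
    for row in concrete.rows:
        cfg = {f: _clamp(row[f], state.factors[f]) for f in active}
        for f, region in state.regions.items():
            if region.frozen and f not in cfg:
                cfg[f] = _clamp(region.center, state.factors[f])
        cfg.update(state.fixed)
        configs.append(cfg)

    records = executor.run(f"iteration-{k}", configs)
    n_bad = sum(1 for r in records if r.status != "ok")
    if n_bad * 2 > len(records):
        if audit is not None:
            for rec in records:
                audit.add(rec)
        raise IterationError(
            f"iteration {k}: {n_bad}/{len(records)} runs failed"
        )
    scored = _score_records(records, state.specs)
    if audit is not None:
        for rec in records:
            audit.add(rec)
        audit.attach_scores(scored)
    rec_by_id = {r.run_id: r for r in records}

    # fit one model per response on the successful runs
    ok = [r for r in records if r.status == "ok"]
    rows = [{f: float(r.configuration[f]) for f in active} for r in ok]
    method = state.model_selection or (
        "greedy_forward" if len(active) > 4 else "best_subset"
    )
    models: dict[str, sm.SurrogateModel] = {}
    q2_pass = True
    try:
        for spec in state.specs:
            y = [float(r.responses[spec.name]) for r in ok]
            models[spec.name] = sm.select_model(rows, y, method=method)
    except (SelectionError, ValidationError) as exc:
        logger.info("iteration %d: model selection failed (%s)", k, exc)
        models = {}
        q2_pass = False
    if models:
        worst_q2 = min(m.q2 for m in models.values())
        q2_pass = worst_q2 > state.q2_threshold
        logger.info("iteration %d: min Q2 = %.4f", k, worst_q2)

    if q2_pass:
        region = state.region_bounds()
        if len(state.specs) == 1:
            spec = state.specs[0]
            if spec.criterion == "target":
                opt = sm.predict_optimum(
                    models,
                    region,
                    ordinal_factors=state.ordinal_factors(),
                    specs=state.specs,
                    n_grid=state.n_grid,
                )
            else:
                opt = sm.predict_optimum(
                    models[spec.name],
                    region,
                    ordinal_factors=state.ordinal_factors(),
                    goal=spec.criterion,
                    n_grid=state.n_grid,
                )
        else:
            opt = sm.predict_optimum(
                models,
                region,
                ordinal_factors=state.ordinal_factors(),
                specs=state.specs,
                n_grid=state.n_grid,
            )
        val_cfg = {
            f: _clamp(v, state.factors[f]) for f, v in opt.configuration.items()
        }
        for f, r in state.regions.items():
            if r.frozen and f not in val_cfg:
                val_cfg[f] = _clamp(r.center, state.factors[f])
        val_cfg.update(state.fixed)
        val_records = executor.run("validation", [val_cfg])
        val_scored = _score_records(val_records, state.specs)
        if audit is not None:
            for rec in val_records:
                audit.add(rec)
            audit.attach_scores(val_scored)
        records += val_records
        rec_by_id.update({r.run_id: r for r in val_records})
        scored = _score_records(records, state.specs)

    best = scored[0]
    if not best.valid:
        raise IterationError(f"iteration {k}: no valid runs")
    best_config = dict(rec_by_id[best.run_id].configuration)
    record = IterationRecord(
        iteration=k,
        runs=scored,
        models={n: m.summary() for n, m in models.items()} or None,
        moved=False,
        best=best,
        best_config=best_config,
    )
    state.history.append(record)
    return record


def update_design_space(
    state: OptimizationState, best_point: Mapping[str, float]
) -> bool:
    """Move the region toward the iteration best, then shrink and clamp.

    Per factor: if the best point lies more than step_fraction * span from
    the center, the center moves by step_fraction * span in that direction.
    Every span is then multiplied by the shrinkage factor, and regions that
    poke past a global bound are translated inside, span preserved.  Returns
    True when any factor moved.
    """
    moved = False
    for f in state.active_factors:
        region = state.regions[f]
        fac = state.factors[f]
        delta = float(best_point[f]) - region.center
        step = state.step_fraction * region.span
        if abs(delta) > step:
            region.center += math.copysign(step, delta)
            moved = True
        region.span *= state.shrinkage
        if region.span > fac.span:
            region.span = fac.span
        if region.low < fac.minimum:
            region.center += fac.minimum - region.low
        if region.high > fac.maximum:
            region.center -= region.high - fac.maximum
        min_span = 1.0 if fac.kind == dz.ORDINAL else 1e-9 * fac.span
        if region.span < min_span:
            region.frozen = True
            logger.warning(
                "factor %s frozen at %.6g (span %.3g below resolution)",
                f,
                region.center,
                region.span,
            )
    state.assert_containment()
    return moved


def check_convergence(
    state: OptimizationState,
    moved: bool,
    best_value: float,
    previous_best_value: float,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> tuple[bool, str]:
    """Halting rule after one completed iteration."""
    if state.iteration < 1:
        raise ValidationError("convergence check needs >= 1 iteration")
    if not moved:
        return True, "design unmoved"
    if best_value <= previous_best_value:
        return True, "no improvement"
    if state.iteration >= max_iterations:
        return True, "iteration cap reached"
    if not state.active_factors:
        return True, "all factors frozen"
    return False, "continue"


@dataclass
class OptimizationReport:
    best_configuration: dict
    best_scored: ScoredRun
    total_runs: int
    iterations: int
    restarts: int
    halt_reasons: list[str]
    audit: AuditTrail
    screening_best: ScoredRun
    #: (attempt, iteration, {factor: span}) snapshots taken after each update
    span_history: list[tuple[int, int, dict]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_configuration": self.best_configuration,
            "best_responses": dict(self.best_scored.responses),
            "best_desirabilities": dict(self.best_scored.desirabilities),
            "best_overall": self.best_scored.overall,
            "best_run_id": self.best_scored.run_id,
            "total_runs": self.total_runs,
            "iterations": self.iterations,
            "restarts": self.restarts,
            "halt_reasons": self.halt_reasons,
        }


def _acceptable(scored: ScoredRun, specs: Sequence[ResponseSpec]) -> bool:
    """True when every response clears its minimally acceptable limit."""
    for spec in specs:
        if not spec.scorable:
            continue
        if desirability_score(float(scored.responses[spec.name]), spec) <= 0.0:
            return False
    return True


def optimize(
    factors: Sequence[dz.Factor],
    specs: Sequence[ResponseSpec],
    executor: Executor,
    *,
    reduction: int | None = None,
    levels: Mapping[str, int] | int | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
    step_fraction: float = DEFAULT_STEP_FRACTION,
    q2_threshold: float = DEFAULT_Q2_THRESHOLD,
    model_selection: str | None = None,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    max_restarts: int = DEFAULT_MAX_RESTARTS,
    n_grid: int = 51,
) -> OptimizationReport:
    """Full two-phase optimization; returns the best over ALL executed runs."""
    factors = list(factors)
    specs = list(specs)
    if len(specs) > 1:
        for s in specs:
            s.validate_for_desirability()
    audit = AuditTrail()
    screening = run_screening(
        factors, specs, executor, reduction=reduction, levels=levels, audit=audit
    )
    numeric = [f for f in factors if f.is_numeric]

    global_best = screening.best
    global_best_config = dict(screening.best_config)
    halt_reasons: list[str] = []
    span_history: list[tuple[int, int, dict]] = []
    total_iterations = 0
    restarts_used = 0

    def consider(scored: ScoredRun, config: dict) -> None:
        nonlocal global_best, global_best_config
        if ranking_key(scored, specs) > ranking_key(global_best, specs):
            global_best = scored
            global_best_config = dict(config)

    if not numeric:
        return OptimizationReport(
            best_configuration=global_best_config,
            best_scored=global_best,
            total_runs=len(audit),
            iterations=0,
            restarts=0,
            halt_reasons=["no numeric factors"],
            audit=audit,
            screening_best=screening.best,
        )

    # distinct screening configurations, best first, for the restart rule
    start_configs: list[dict] = []
    seen: set[tuple] = set()
    for s in screening.scored:
        if not s.valid:
            continue
        cfg = dict(screening.records[s.run_id].configuration)
        key = tuple(sorted((k, v) for k, v in cfg.items()))
        if key not in seen:
            seen.add(key)
            start_configs.append(cfg)

    for attempt, start in enumerate(start_configs[: max_restarts + 1]):
        if attempt > 0:
            restarts_used += 1
            logger.info(
                "restarting optimization from screening candidate %d", attempt
            )
        state = OptimizationState(
            factors={f.name: f for f in factors},
            specs=specs,
            regions=initialize_rsm(start, screening.levels, factors),
            fixed={
                f.name: start[f.name]
                for f in factors
                if f.kind == dz.CATEGORICAL
            },
            shrinkage=shrinkage,
            step_fraction=step_fraction,
            q2_threshold=q2_threshold,
            model_selection=model_selection,
            n_grid=n_grid,
        )
        state.assert_containment()
        start_scored = next(
            s for s in screening.scored if screening.records[s.run_id].configuration == start
        )
        previous_best = ranking_key(start_scored, specs)
        consider(start_scored, start)

        while True:
            try:
                record = run_iteration(state, executor, audit=audit)
            except IterationError as exc:
                halt_reasons.append(str(exc))
                break
            total_iterations += 1
            consider(record.best, record.best_config)
            moved = update_design_space(state, record.best_config)
            record.moved = moved
            span_history.append(
                (
                    attempt,
                    state.iteration,
                    {f: r.span for f, r in state.regions.items()},
                )
            )
            best_value = ranking_key(record.best, specs)
            halt, reason = check_convergence(
                state, moved, best_value, previous_best, max_iterations
            )
            previous_best = max(previous_best, best_value)
            if halt:
                halt_reasons.append(reason)
                break

        if _acceptable(global_best, specs):
            break

    return OptimizationReport(
        best_configuration=global_best_config,
        best_scored=global_best,
        total_runs=len(audit),
        iterations=total_iterations,
        restarts=restarts_used,
        halt_reasons=halt_reasons,
        audit=audit,
        screening_best=screening.best,
        span_history=span_history,
    )
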