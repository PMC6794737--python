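import math

import numpy as np
import pytest

from doeopt import Factor, MockExecutor, MockObjective, ResponseSpec
from doeopt import optimizer as opt
from doeopt.design import ScreeningLevels
from doeopt.desirability import ranking_key
from doeopt.errors import IterationError, ScreeningError, ValidationError


def make_state(factors, specs, regions, **kwargs):
    return opt.OptimizationState(
        factors={f.name: f for f in factors},
        specs=list(specs),
        regions=regions,
        fixed={},
        **kwargs,
    )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


class TestScreening:
    def test_best_at_grid_point(self, two_factor_space, single_maximize_spec):
        # optimum exactly on a screened grid point that the GSD retains:
        # level indices (2, 2) have even class sum under reduction 2
        obj = MockObjective(
            optima={"a": 5.0, "b": 5.0}, curvatures={"a": 1.0, "b": 1.0}, y0=1.0
        )
        ex = MockExecutor(obj)
        res = opt.run_screening(
            two_factor_space, single_maximize_spec, ex, reduction=2, levels=5
        )
        assert res.best_config == {"a": 5.0, "b": 5.0}
        assert res.best.overall == pytest.approx(1.0)

    def test_gsd_subset_is_executed(self, two_factor_space, single_maximize_spec):
        obj = MockObjective(
            optima={"a": 5.0, "b": 5.0}, curvatures={"a": 1.0, "b": 1.0}
        )
        ex = MockExecutor(obj)
        opt.run_screening(
            two_factor_space, single_maximize_spec, ex, reduction=2, levels=5
        )
        assert len(ex.records) == 13  # half fraction of 5x5, class-sum rule

    def test_categorical_fixed_at_best(self, single_maximize_spec):
        factors = [
            Factor("alg", "categorical", categories=("A", "B")),
            Factor("x", "quantitative", 0, 10),
        ]
        obj = MockObjective(
            optima={"x": 5.0},
            curvatures={"x": 0.01},
            categorical_offsets={("alg", "A"): 0.0, ("alg", "B"): 0.7},
            y0=1.0,
        )
        ex = MockExecutor(obj)
        res = opt.run_screening(factors, single_maximize_spec, ex)
        assert res.fixed_categoricals == {"alg": "B"}

    def test_all_failures_raise(self, two_factor_space, single_maximize_spec):
        obj = MockObjective(
            optima={"a": 5.0, "b": 5.0}, curvatures={"a": 1.0, "b": 1.0}
        )
        ex = MockExecutor(obj, fail_predicate=lambda cfg: True)
        with pytest.raises(ScreeningError):
            opt.run_screening(two_factor_space, single_maximize_spec, ex)

    def test_default_reduction_is_factor_count(self, single_maximize_spec):
        factors = [Factor(n, "quantitative", 0, 10) for n in "abcd"]
        obj = MockObjective(
            optima={n: 5.0 for n in "abcd"},
            curvatures={n: 0.01 for n in "abcd"},
        )
        ex = MockExecutor(obj)
        opt.run_screening(factors, single_maximize_spec, ex)
        # [5,5,5,5] at reduction 4: class-sum rule gives 157 runs for index 0
        assert len(ex.records) == 157


# ---------------------------------------------------------------------------
# region initialization
# ---------------------------------------------------------------------------


class TestAnchorInterval:
    def test_interior_best(self):
        center, low, high = opt.anchor_interval((2, 5.25, 8.5, 11.75, 15), 8.5)
        assert center == 8.5
        assert low == pytest.approx(6.875)
        assert high == pytest.approx(10.125)
        assert high - low == pytest.approx(3.25)

    def test_edge_best_shifts_inward(self):
        center, low, high = opt.anchor_interval((20, 30, 40, 50, 60), 60)
        assert center == 50
        assert (low, high) == (45, 55)

    def test_uneven_levels(self):
        center, low, high = opt.anchor_interval((5, 8, 10, 13, 15), 10)
        assert (center, low, high) == (10, 9.0, 11.5)

    def test_needs_three_levels(self):
        with pytest.raises(ValidationError):
            opt.anchor_interval((0, 1), 0)


class TestInitializeRSM:
    def test_spans_and_centers(self):
        factors = [
            Factor("MIKC", "quantitative", 2, 15),
            Factor("MIAL", "ordinal", 20, 60),
        ]
        levels = {
            "MIKC": ScreeningLevels("MIKC", (2, 5.25, 8.5, 11.75, 15)),
            "MIAL": ScreeningLevels("MIAL", (20, 30, 40, 50, 60)),
        }
        regions = opt.initialize_rsm({"MIKC": 8.5, "MIAL": 60}, levels, factors)
        assert regions["MIKC"].center == 8.5
        assert regions["MIKC"].span == pytest.approx(3.25)
        assert regions["MIAL"].center == 50  # shifted inward from the edge
        assert regions["MIAL"].span == pytest.approx(10)

    def test_region_inside_global_bounds(self):
        factors = [Factor("x", "quantitative", 0, 10)]
        levels = {"x": ScreeningLevels("x", (0, 2.5, 5, 7.5, 10))}
        regions = opt.initialize_rsm({"x": 0.0}, levels, factors)
        assert regions["x"].low >= 0.0
        assert regions["x"].high <= 10.0

    def test_categoricals_skipped(self):
        factors = [
            Factor("x", "quantitative", 0, 10),
            Factor("c", "categorical", categories=("u", "v")),
        ]
        levels = {"x": ScreeningLevels("x", (0, 2.5, 5, 7.5, 10))}
        regions = opt.initialize_rsm({"x": 5.0, "c": "u"}, levels, factors)
        assert set(regions) == {"x"}


# ---------------------------------------------------------------------------
# design-space update
# ---------------------------------------------------------------------------


class TestUpdateDesignSpace:
    def make(self, center, span, fmin=0.0, fmax=100.0, shrinkage=0.9):
        factors = [Factor("x", "quantitative", fmin, fmax)]
        state = make_state(
            factors,
            [ResponseSpec("y", "maximize")],
            {"x": opt.FactorRegion(center=center, span=span)},
            shrinkage=shrinkage,
        )
        return state

    def test_moves_by_step_fraction(self):
        state = self.make(50.0, 20.0)
        moved = opt.update_design_space(state, {"x": 56.0})
        region = state.regions["x"]
        assert moved
        assert region.center == pytest.approx(55.0)  # moved by 0.25 * 20
        assert region.span == pytest.approx(18.0)  # then shrunk by 0.9
        assert (region.low, region.high) == (pytest.approx(46.0), pytest.approx(64.0))

    def test_within_step_no_move_only_shrink(self):
        state = self.make(50.0, 20.0)
        moved = opt.update_design_space(state, {"x": 50.0})
        assert not moved
        assert state.regions["x"].center == 50.0
        assert state.regions["x"].span == pytest.approx(18.0)

    def test_clamp_translates_keeping_span(self):
        state = self.make(9.0, 4.0, fmin=0.0, fmax=10.0)
        moved = opt.update_design_space(state, {"x": 9.0})
        region = state.regions["x"]
        assert not moved
        assert region.span == pytest.approx(3.6)
        assert region.high == pytest.approx(10.0)
        assert region.low == pytest.approx(6.4)

    def test_move_direction_negative(self):
        state = self.make(50.0, 20.0)
        opt.update_design_space(state, {"x": 40.0})
        assert state.regions["x"].center == pytest.approx(45.0)

    def test_span_freeze_for_ordinal(self):
        factors = [Factor("k", "ordinal", 0, 100)]
        state = make_state(
            factors,
            [ResponseSpec("y", "maximize")],
            {"k": opt.FactorRegion(center=50.0, span=1.05)},
        )
        opt.update_design_space(state, {"k": 50.0})
        assert state.regions["k"].frozen  # 1.05 * 0.9 < 1

    def test_containment_asserted(self):
        state = self.make(50.0, 20.0)
        for _ in range(10):
            opt.update_design_space(state, {"x": 95.0})
            region = state.regions["x"]
            assert region.low >= 0.0 - 1e-9 and region.high <= 100.0 + 1e-9


class TestCheckConvergence:
    def make_state(self, iteration=1):
        factors = [Factor("x", "quantitative", 0, 10)]
        state = make_state(
            factors,
            [ResponseSpec("y", "maximize")],
            {"x": opt.FactorRegion(center=5.0, span=2.0)},
        )
        state.iteration = iteration
        return state

    def test_unmoved_halts(self):
        halt, reason = opt.check_convergence(self.make_state(), False, 0.7, 0.6)
        assert halt and reason == "design unmoved"

    def test_no_improvement_halts(self):
        halt, reason = opt.check_convergence(self.make_state(), True, 0.6, 0.6)
        assert halt and reason == "no improvement"

    def test_improvement_continues(self):
        halt, reason = opt.check_convergence(self.make_state(), True, 0.6, 0.5)
        assert not halt and reason == "continue"

    def test_iteration_cap(self):
        halt, reason = opt.check_convergence(
            self.make_state(iteration=25), True, 0.9, 0.5, max_iterations=25
        )
        assert halt and reason == "iteration cap reached"

    def test_requires_an_iteration(self):
        with pytest.raises(ValidationError):
            opt.check_convergence(self.make_state(iteration=0), True, 1, 0)


# ---------------------------------------------------------------------------
# iterations
# ---------------------------------------------------------------------------


class TestRunIteration:
    def setup_state(self, objective, factors, specs, **kwargs):
        return make_state(
            factors,
            specs,
            {
                f.name: opt.FactorRegion(center=5.0, span=2.5)
                for f in factors
                if f.is_numeric
            },
            **kwargs,
        )

    def test_validation_run_at_model_vertex(
        self, two_factor_space, single_maximize_spec
    ):
        obj = MockObjective(
            optima={"a": 5.2, "b": 4.9}, curvatures={"a": 0.5, "b": 0.5}, y0=1.0
        )
        ex = MockExecutor(obj)
        state = self.setup_state(obj, two_factor_space, single_maximize_spec)
        record = opt.run_iteration(state, ex)
        assert len(ex.records) == 10  # 9 CCF runs + 1 validation
        assert ex.records[-1].phase == "validation"
        assert record.best.run_id == ex.records[-1].run_id
        assert record.best_config["a"] == pytest.approx(5.2, abs=0.05)
        assert record.best_config["b"] == pytest.approx(4.9, abs=0.05)

    def test_noise_skips_validation(self, two_factor_space, single_maximize_spec):
        obj = MockObjective(
            optima={"a": 5.0, "b": 5.0},
            curvatures={"a": 1e-6, "b": 1e-6},
            noise_sd=1.0,
            seed=123,
        )
        ex = MockExecutor(obj)
        state = self.setup_state(obj, two_factor_space, single_maximize_spec)
        record = opt.run_iteration(state, ex)
        assert len(ex.records) == 9  # q2 gate failed: no validation run
        assert record.models is None or all(
            m["q2"] <= 0.5 for m in record.models.values()
        )
        # iteration best is still the best observed CCF run
        best_key = max(ranking_key(s, state.specs) for s in record.runs)
        assert ranking_key(record.best, state.specs) == best_key

    def test_ccf_run_count_two_factors(
        self, two_factor_space, single_maximize_spec, quadratic_objective
    ):
        ex = MockExecutor(quadratic_objective)
        state = self.setup_state(
            quadratic_objective, two_factor_space, single_maximize_spec
        )
        opt.run_iteration(state, ex)
        assert len(ex.records) in (9, 10)

    def test_majority_failures_raise(
        self, two_factor_space, single_maximize_spec, quadratic_objective
    ):
        ex = MockExecutor(quadratic_objective, fail_predicate=lambda cfg: cfg["a"] > 4)
        state = self.setup_state(
            quadratic_objective, two_factor_space, single_maximize_spec
        )
        with pytest.raises(IterationError):
            opt.run_iteration(state, ex)

    def test_ordinal_configs_are_integers(self, single_maximize_spec):
        factors = [Factor("k", "ordinal", 0, 10), Factor("x", "quantitative", 0, 10)]
        obj = MockObjective(
            optima={"k": 5.0, "x": 5.0}, curvatures={"k": 0.5, "x": 0.5}, y0=1.0
        )
        ex = MockExecutor(obj)
        state = make_state(
            factors,
            single_maximize_spec,
            {
                "k": opt.FactorRegion(center=5.0, span=2.5),
                "x": opt.FactorRegion(center=5.0, span=2.5),
            },
        )
        opt.run_iteration(state, ex)
        assert all(isinstance(r.configuration["k"], int) for r in ex.records)


# ---------------------------------------------------------------------------
# full optimization
# ---------------------------------------------------------------------------


class TestOptimize:
    def test_recovers_interior_optimum(
        self, two_factor_space, single_maximize_spec, quadratic_objective
    ):
        ex = MockExecutor(quadratic_objective)
        report = opt.optimize(
            two_factor_space, single_maximize_spec, ex, model_selection="best_subset"
        )
        for name, true_opt in quadratic_objective.optima.items():
            assert abs(report.best_configuration[name] - true_opt) <= 1.0  # 10% of range

    def test_budget_accounting(
        self, two_factor_space, single_maximize_spec, quadratic_objective
    ):
        ex = MockExecutor(quadratic_objective)
        report = opt.optimize(two_factor_space, single_maximize_spec, ex)
        assert report.total_runs == len(ex.records)
        audit_ids = [r.run_id for r in report.audit.records]
        assert audit_ids == [r.run_id for r in ex.records]
        assert len(set(audit_ids)) == len(audit_ids)

    def test_reported_best_is_audit_argmax(
        self, two_factor_space, single_maximize_spec, quadratic_objective
    ):
        ex = MockExecutor(quadratic_objective)
        report = opt.optimize(two_factor_space, single_maximize_spec, ex)
        ok = [r for r in report.audit.records if r.status == "ok"]
        best_raw = max(r.responses["y"] for r in ok)
        assert report.best_scored.responses["y"] == pytest.approx(best_raw)

    def test_never_worse_than_screening(
        self, two_factor_space, single_maximize_spec, quadratic_objective
    ):
        ex = MockExecutor(quadratic_objective)
        report = opt.optimize(two_factor_space, single_maximize_spec, ex)
        specs = single_maximize_spec
        assert ranking_key(report.best_scored, specs) >= ranking_key(
            report.screening_best, specs
        )

    def test_all_categorical_degenerate(self):
        factors = [
            Factor("c1", "categorical", categories=("a", "b")),
            Factor("c2", "categorical", categories=("u", "v", "w")),
        ]
        obj = MockObjective(
            optima={},
            curvatures={},
            categorical_offsets={
                ("c1", "a"): 0.0,
                ("c1", "b"): 0.3,
                ("c2", "u"): 0.0,
                ("c2", "v"): 0.5,
                ("c2", "w"): 0.1,
            },
            y0=1.0,
        )
        ex = MockExecutor(obj)
        report = opt.optimize(factors, [ResponseSpec("y", "maximize")], ex)
        assert report.iterations == 0
        assert report.halt_reasons == ["no numeric factors"]
        assert report.best_configuration == {"c1": "b", "c2": "v"}

    def test_restart_reaches_second_basin(self, fn_executor):
        # y2 is acceptable only in (80, 94), which no screening level hits;
        # only the restart from the highest screening start can reach it
        factors = [Factor("x", "quantitative", 0, 100)]
        specs = [
            ResponseSpec("y1", "maximize", low_limit=0.0, target=1.0),
            ResponseSpec("y2", "maximize", low_limit=0.0, target=1.0),
        ]

        def surface(cfg):
            x = cfg["x"]
            return {"y1": x / 100.0, "y2": 1.0 - abs(x - 87.0) / 7.0}

        ex = fn_executor(surface)
        report = opt.optimize(factors, specs, ex, levels=5)
        assert report.restarts >= 1
        assert report.best_scored.overall > 0.0
        assert all(d > 0 for d in report.best_scored.desirabilities.values())

    def test_span_monotonicity_over_iterations(
        self, two_factor_space, single_maximize_spec
    ):
        obj = MockObjective(
            optima={"a": 8.0, "b": 2.0}, curvatures={"a": 0.05, "b": 0.05}, y0=1.0
        )
        ex = MockExecutor(obj)
        levels = {
            "a": ScreeningLevels("a", (0, 2.5, 5, 7.5, 10)),
            "b": ScreeningLevels("b", (0, 2.5, 5, 7.5, 10)),
        }
        state = make_state(
            two_factor_space,
            single_maximize_spec,
            opt.initialize_rsm({"a": 7.5, "b": 2.5}, levels, two_factor_space),
        )
        spans = {f: [state.regions[f].span] for f in state.regions}
        for _ in range(4):
            record = opt.run_iteration(state, ex)
            opt.update_design_space(state, record.best_config)
            for f in state.regions:
                assert state.regions[f].span <= spans[f][-1] * 0.9 + 1e-12
                spans[f].append(state.regions[f].span)

    def test_deterministic_given_inputs(
        self, two_factor_space, single_maximize_spec, quadratic_objective
    ):
        reports = []
        for _ in range(2):
            ex = MockExecutor(quadratic_objective)
            reports.append(
                opt.optimize(two_factor_space, single_maximize_spec, ex)
            )
        assert reports[0].best_configuration == reports[1].best_configuration
        assert reports[0].total_runs == reports[1].total_runs
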