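from __future__ import annotations

import pytest

from doeopt import Factor, MockObjective, ResponseSpec
from doeopt.runs import RunRecord, STATUS_FAILED, STATUS_OK


class FnExecutor:
    """Executor evaluating an arbitrary callable configuration -> responses.

    Lets tests shape response surfaces that the quadratic MockObjective
    cannot express (two-basin restarts, plateaus, ...).
    """

    def __init__(self, fn, fail_predicate=None):
        self.fn = fn
        self.fail_predicate = fail_predicate
        self._counter = 0
        self.records: list[RunRecord] = []

    def run(self, phase, configurations):
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
            else:
                rec.responses = dict(self.fn(cfg))
                rec.status = STATUS_OK
            out.append(rec)
            self.records.append(rec)
        return out


@pytest.fixture
def fn_executor():
    return FnExecutor


@pytest.fixture
def two_factor_space():
    return [
        Factor("a", "quantitative", 0, 10),
        Factor("b", "quantitative", 0, 10),
    ]


@pytest.fixture
def single_maximize_spec():
    return [ResponseSpec("y", "maximize")]


@pytest.fixture
def assembly_specs():
    """The three-response declaration of the de-novo assembly benchmark."""
    return [
        ResponseSpec("tSeq", "maximize", low_limit=1_830_000, target=1_894_157),
        ResponseSpec("nSeq", "minimize", high_limit=95, target=85),
        ResponseSpec("N50", "maximize", low_limit=28_000, target=35_000),
    ]


@pytest.fixture
def quadratic_objective():
    return MockObjective(
        optima={"a": 3.3, "b": 7.1},
        curvatures={"a": 0.02, "b": 0.03},
        y0=1.0,
    )
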