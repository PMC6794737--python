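"""Run records, the audit trail, and the executor protocol shared by the
screening/optimization controller, the pipeline runner, and the mock
benchmark executors."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import pandas as pd

from .desirability import ScoredRun

STATUS_OK = "ok"
STATUS_FAILED = "failed"
STATUS_INVALID = "invalid"


@dataclass
class RunRecord:
    """One pipeline execution: configuration in, responses (or failure) out."""

    run_id: str
    phase: str
    configuration: dict
    status: str = "pending"
    responses: dict = field(default_factory=dict)
    scripts: list = field(default_factory=list)
    workdir: str | None = None
    note: str = ""
    timestamp: float = field(default_factory=time.time)


@runtime_checkable
class Executor(Protocol):
    """Anything that can execute a batch of concrete configurations.

    Implementations must assign globally unique, monotonically increasing
    run ids (string-sortable) and return one :class:`RunRecord` per input
    configuration, in input order.
    """

    def run(
        self, phase: str, configurations: Sequence[Mapping]
    ) -> list[RunRecord]: ...


class AuditTrail:
    """Append-only log of every executed run plus its scores."""

    def __init__(self) -> None:
        self.records: list[RunRecord] = []
        self.scores: dict[str, ScoredRun] = {}

    def add(self, record: RunRecord, scored: ScoredRun | None = None) -> None:
        self.records.append(record)
        if scored is not None:
            self.scores[record.run_id] = scored

    def attach_scores(self, scored_runs: Sequence[ScoredRun]) -> None:
        for s in scored_runs:
            self.scores[s.run_id] = s

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        factor_names: list[str] = []
        response_names: list[str] = []
        for rec in self.records:
            for f in rec.configuration:
                if f not in factor_names:
                    factor_names.append(f)
            for r in rec.responses:
                if r not in response_names:
                    response_names.append(r)
        des_names = sorted(
            {name for s in self.scores.values() for name in s.desirabilities}
        )
        rows = []
        for rec in self.records:
            row: dict = {"run_id": rec.run_id, "phase": rec.phase}
            for f in factor_names:
                row[f] = rec.configuration.get(f)
            for r in response_names:
                row[r] = rec.responses.get(r)
            scored = self.scores.get(rec.run_id)
            for d in des_names:
                row[f"d_{d}"] = (
                    scored.desirabilities.get(d) if scored is not None else None
                )
            row["overall"] = scored.overall if scored is not None else None
            row["status"] = rec.status
            row["timestamp"] = rec.timestamp
            rows.append(row)
        columns = (
            ["run_id", "phase"]
            + factor_names
            + response_names
            + [f"d_{d}" for d in des_names]
            + ["overall", "status", "timestamp"]
        )
        return pd.DataFrame(rows, columns=columns)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
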