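"""Experimental designs: screening levels, generalized subset designs (GSD),
full factorials, central composite face-centered (CCF) designs, and decoding
of abstract designs into concrete factor configurations.

Designs are represented by :class:`DesignMatrix`, whose rows are plain
mappings ``factor name -> value``.  Three forms exist:

``level-index``
    integer indices into a factor's screening levels (GSD, full factorial)
``coded``
    values in {-1, 0, +1} relative to a (center, span) region (CCF)
``concrete``
    executable factor settings (after :func:`decode_design`)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ResolutionError, ValidationError

QUANTITATIVE = "quantitative"
ORDINAL = "ordinal"
CATEGORICAL = "categorical"
NUMERIC_KINDS = (QUANTITATIVE, ORDINAL)

#: default screening resolution for numeric factors
DEFAULT_N_LEVELS = 5

#: maximum number of factors in a CCF design
CCF_FACTOR_CAP = 8


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (37.5 -> 38)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Factor:
    """One tunable pipeline parameter.

    Numeric kinds (``quantitative``, ``ordinal``) are bounded by
    ``minimum``/``maximum``; categorical factors carry an ordered tuple of
    category labels instead.
    """

    name: str
    kind: str
    minimum: float | None = None
    maximum: float | None = None
    categories: tuple[str, ...] = ()
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValidationError("factor name must be a non-empty string")
        if self.kind not in NUMERIC_KINDS + (CATEGORICAL,):
            raise ValidationError(
                f"factor {self.name!r}: unknown kind {self.kind!r}"
            )
        if self.is_numeric:
            if self.minimum is None or self.maximum is None:
                raise ValidationError(
                    f"factor {self.name!r}: numeric factors need min and max"
                )
            if not (self.minimum < self.maximum):
                raise ValidationError(
                    f"factor {self.name!r}: min must be < max "
                    f"({self.minimum} >= {self.maximum})"
                )
            if self.kind == ORDINAL:
                if self.minimum != int(self.minimum) or self.maximum != int(
                    self.maximum
                ):
                    raise ValidationError(
                        f"factor {self.name!r}: ordinal bounds must be integers"
                    )
        else:
            if len(self.categories) < 2:
                raise ValidationError(
                    f"factor {self.name!r}: categorical factors need >= 2 "
                    "categories"
                )
            if len(set(self.categories)) != len(self.categories):
                raise ValidationError(
                    f"factor {self.name!r}: duplicate categories"
                )
        n = self.resolved_n_levels
        if n < 2:
            raise ValidationError(
                f"factor {self.name!r}: n_levels must be >= 2 (got {n})"
            )

    @property
    def is_numeric(self) -> bool:
        return self.kind in NUMERIC_KINDS

    @property
    def resolved_n_levels(self) -> int:
        if self.n_levels is not None:
            return self.n_levels
        if self.kind == CATEGORICAL:
            return len(self.categories)
        return DEFAULT_N_LEVELS

    @property
    def span(self) -> float:
        if not self.is_numeric:
            raise ValidationError(f"factor {self.name!r} has no numeric span")
        return float(self.maximum) - float(self.minimum)


@dataclass(frozen=True)
class ScreeningLevels:
    """Ordered concrete settings tested for one factor during screening."""

    name: str
    values: tuple

    def __len__(self) -> int:
        return len(self.values)


def screening_levels(factor: Factor, n_levels: int | None = None) -> ScreeningLevels:
    """Equally spaced screening levels from min to max inclusive.

    Ordinal levels are rounded half-up to integers; a duplicate after
    rounding means the requested resolution exceeds the factor's range and
    raises :class:`ResolutionError`.  Categorical factors return their
    category labels unchanged.
    """
    if factor.kind == CATEGORICAL:
        return ScreeningLevels(factor.name, tuple(factor.categories))
    n = factor.resolved_n_levels if n_levels is None else n_levels
    if n < 2:
        raise ValidationError(
            f"factor {factor.name!r}: need at least 2 screening levels"
        )
    raw = np.linspace(float(factor.minimum), float(factor.maximum), n)
    if factor.kind == ORDINAL:
        values = tuple(round_half_up(v) for v in raw)
        if len(set(values)) != len(values):
            raise ResolutionError(
                f"factor {factor.name!r}: {n} levels collapse after integer "
                f"rounding over [{factor.minimum}, {factor.maximum}]"
            )
    else:
        values = tuple(float(v) for v in raw)
    return ScreeningLevels(factor.name, values)


@dataclass(frozen=True)
class DesignMatrix:
    """An ordered run plan: one row per run, one entry per factor."""

    form: str  # level-index | coded | concrete
    factor_names: tuple[str, ...]
    rows: tuple
    provenance: str  # gsd | full_factorial | ccf | validation
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for row in self.rows:
            if set(row) != set(self.factor_names):
                raise ValidationError(
                    "design row does not assign exactly the declared factors"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def row_tuples(self) -> list[tuple]:
        return [tuple(row[f] for f in self.factor_names) for row in self.rows]

    def to_dataframe(self, phase: str = "") -> pd.DataFrame:
        df = pd.DataFrame(list(self.rows), columns=list(self.factor_names))
        df.insert(0, "run_id", [f"run{i:04d}" for i in range(len(df))])
        df.insert(1, "phase", phase)
        df.insert(2, "provenance", self.provenance)
        return df

    def to_csv(self, path, phase: str = "") -> None:
        self.to_dataframe(phase).to_csv(path, index=False)


def _sorted_matrix(form, names, tuples, provenance, meta=None):
    rows = tuple(dict(zip(names, t)) for t in sorted(tuples))
    return DesignMatrix(form, tuple(names), rows, provenance, meta or {})


def generate_gsd(
    level_counts: Sequence[int],
    reduction: int,
    complementary_index: int = 0,
    names: Sequence[str] | None = None,
) -> DesignMatrix:
    """Generalized subset design in level-index form.

    Level indices of each factor are partitioned cyclically into
    ``reduction`` classes (index i -> class i mod reduction); the design is
    the union of Cartesian products of class tuples whose class-sum is
    congruent to ``complementary_index`` modulo ``reduction``.  The
    ``reduction`` complementary designs partition the full factorial.
    """
    level_counts = [int(n) for n in level_counts]
    if not level_counts or any(n < 1 for n in level_counts):
        raise ValidationError("level_counts must be positive integers")
    total = math.prod(level_counts)
    if not (2 <= reduction <= total):
        raise ValidationError(
            f"reduction must be in [2, {total}] (got {reduction})"
        )
    if not (0 <= complementary_index < reduction):
        raise ValidationError(
            f"complementary_index must be in [0, {reduction - 1}]"
        )
    k = len(level_counts)
    if names is None:
        names = [f"f{i}" for i in range(k)]
    classes = [
        {c: [i for i in range(n) if i % reduction == c] for c in range(reduction)}
        for n in level_counts
    ]
    tuples: list[tuple[int, ...]] = []
    for combo in itertools.product(range(reduction), repeat=k):
        if sum(combo) % reduction != complementary_index:
            continue
        members = [classes[j][combo[j]] for j in range(k)]
        if any(not m for m in members):
            continue
        tuples.extend(itertools.product(*members))
    meta = {"reduction": reduction, "complementary_index": complementary_index}
    return _sorted_matrix("level-index", names, tuples, "gsd", meta)


def generate_full_factorial(
    level_counts: Sequence[int], names: Sequence[str] | None = None
) -> DesignMatrix:
    """All level-index combinations, in lexicographic order."""
    level_counts = [int(n) for n in level_counts]
    if not level_counts:
        raise ValidationError("level_counts must be non-empty")
    if any(n < 1 for n in level_counts):
        raise ValidationError("level counts must be >= 1")
    if names is None:
        names = [f"f{i}" for i in range(len(level_counts))]
    tuples = itertools.product(*(range(n) for n in level_counts))
    return _sorted_matrix("level-index", names, tuples, "full_factorial")


def generate_ccf(
    n_factors: int,
    names: Sequence[str] | None = None,
    cap: int = CCF_FACTOR_CAP,
) -> DesignMatrix:
    """Central composite face-centered design in coded form.

    2^k factorial corners, 2k face-centered axial runs, and exactly one
    center run: 2^k + 2k + 1 rows.
    """
    if not (1 <= n_factors <= cap):
        raise ValidationError(
            f"n_factors must be in [1, {cap}] (got {n_factors})"
        )
    if names is None:
        names = [f"f{i}" for i in range(n_factors)]
    tuples = [tuple(itertools.repeat(0, n_factors))]
    tuples.extend(itertools.product((-1, 1), repeat=n_factors))
    for j in range(n_factors):
        for v in (-1, 1):
            row = [0] * n_factors
            row[j] = v
            tuples.append(tuple(row))
    return _sorted_matrix("coded", names, tuples, "ccf")


def decode_design(
    matrix: DesignMatrix,
    context: Mapping[str, ScreeningLevels | tuple],
    ordinal_factors: Iterable[str] = (),
) -> DesignMatrix:
    """Map an abstract design onto concrete factor settings.

    ``context`` supplies, per factor, either :class:`ScreeningLevels`
    (required for level-index form) or a ``(center, span)`` pair (required
    for coded form; coded -1/0/+1 map to center - span/2, center,
    center + span/2).  Ordinal outputs are rounded half-up.  No clamping to
    global bounds happens here — decoding is purely affine plus rounding.
    """
    ordinal_factors = set(ordinal_factors)
    missing = [f for f in matrix.factor_names if f not in context]
    if missing:
        raise ValidationError(f"decode context missing factors: {missing}")

    def decode_value(name, value):
        ctx = context[name]
        if matrix.form == "level-index":
            if not isinstance(ctx, ScreeningLevels):
                raise ValidationError(
                    f"factor {name!r}: level-index decoding needs ScreeningLevels"
                )
            if not (0 <= value < len(ctx.values)):
                raise ValidationError(
                    f"factor {name!r}: level index {value} out of range"
                )
            return ctx.values[value]
        if matrix.form == "coded":
            if isinstance(ctx, ScreeningLevels):
                raise ValidationError(
                    f"factor {name!r}: coded decoding needs (center, span)"
                )
            center, span = ctx
            out = center + value * span / 2.0
            if name in ordinal_factors:
                return round_half_up(out)
            return float(out)
        raise ValidationError(f"cannot decode design of form {matrix.form!r}")

    rows = tuple(
        {name: decode_value(name, row[name]) for name in matrix.factor_names}
        for row in matrix.rows
    )
    return DesignMatrix(
        "concrete", matrix.factor_names, rows, matrix.provenance, dict(matrix.meta)
    )
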