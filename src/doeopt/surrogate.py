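"""OLS response-surface surrogates.

Models are polynomials over the active numeric factors with terms drawn from
{intercept, linear, two-way interaction, pure quadratic}.  Fitting happens in
coded [-1, 1] units derived from the data; predictive power is the
leave-one-out cross-validated Q2 = 1 - PRESS/SST, computed exactly through
the hat-matrix identity.  Term selection is exhaustive best-subset or greedy
forward under the Q2 criterion, and the in-region optimum of a selected model
is located by dense grid search.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .desirability import (
    MAXIMIZE,
    MINIMIZE,
    ResponseSpec,
    desirability_array,
)
from .errors import FitError, SelectionError, ValidationError

_KIND_RANK = {"intercept": 0, "linear": 1, "interaction": 2, "quadratic": 3}


@dataclass(frozen=True)
class Term:
    kind: str
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KIND_RANK:
            raise ValidationError(f"unknown term kind {self.kind!r}")
        want = {"intercept": 0, "linear": 1, "interaction": 2, "quadratic": 1}
        if len(self.factors) != want[self.kind]:
            raise ValidationError(
                f"term kind {self.kind!r} takes {want[self.kind]} factors"
            )
        if self.kind == "interaction":
            if self.factors[0] == self.factors[1]:
                raise ValidationError("interaction needs two distinct factors")
            if tuple(sorted(self.factors)) != self.factors:
                raise ValidationError("interaction factors must be sorted")

    @property
    def sort_key(self):
        return (_KIND_RANK[self.kind], self.factors)

    def label(self) -> str:
        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return self.factors[0]
        if self.kind == "interaction":
            return f"{self.factors[0]}*{self.factors[1]}"
        return f"{self.factors[0]}^2"


def intercept() -> Term:
    return Term("intercept")


def linear(f: str) -> Term:
    return Term("linear", (f,))


def interaction(f: str, g: str) -> Term:
    return Term("interaction", tuple(sorted((f, g))))


def quadratic(f: str) -> Term:
    return Term("quadratic", (f,))


def candidate_terms(
    factor_names: Sequence[str],
    interactions: bool = True,
    quadratics: bool = True,
) -> list[Term]:
    """Default candidate pool: linear + two-way interactions + quadratics."""
    names = list(factor_names)
    terms = [linear(f) for f in names]
    if interactions:
        terms += [interaction(f, g) for f, g in itertools.combinations(names, 2)]
    if quadratics:
        terms += [quadratic(f) for f in names]
    return terms


def normalize_terms(terms: Iterable[Term]) -> tuple[Term, ...]:
    """Force the intercept in, drop duplicates, order deterministically."""
    out = {intercept()}
    out.update(terms)
    return tuple(sorted(out, key=lambda t: t.sort_key))


def _term_column(term: Term, coded: Mapping[str, np.ndarray]) -> np.ndarray:
    n = len(next(iter(coded.values())))
    if term.kind == "intercept":
        return np.ones(n)
    if term.kind == "linear":
        return coded[term.factors[0]]
    if term.kind == "interaction":
        return coded[term.factors[0]] * coded[term.factors[1]]
    return coded[term.factors[0]] ** 2


def _coding_from_rows(
    rows: Sequence[Mapping[str, float]], factor_names: Sequence[str]
) -> dict[str, tuple[float, float]]:
    coding = {}
    for f in factor_names:
        vals = np.array([float(r[f]) for r in rows])
        mid = (vals.max() + vals.min()) / 2.0
        half = (vals.max() - vals.min()) / 2.0
        coding[f] = (mid, half if half > 0 else 1.0)
    return coding


def _code(
    values: Mapping[str, np.ndarray], coding: Mapping[str, tuple[float, float]]
) -> dict[str, np.ndarray]:
    return {
        f: (np.asarray(values[f], dtype=float) - mid) / half
        for f, (mid, half) in coding.items()
    }


@dataclass(frozen=True)
class SurrogateModel:
    """A fitted OLS polynomial over coded factor coordinates."""

    terms: tuple[Term, ...]
    coefficients: Mapping[Term, float]
    r2: float
    q2: float
    n_runs: int
    coding: Mapping[str, tuple[float, float]]
    factor_names: tuple[str, ...]

    def predict_columns(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Predict over parallel arrays of natural-unit factor values."""
        coded = _code(values, self.coding)
        out = np.zeros(len(next(iter(coded.values()))))
        for term in self.terms:
            out += self.coefficients[term] * _term_column(term, coded)
        return out

    def predict(self, configuration: Mapping[str, float]) -> float:
        cols = {f: np.array([configuration[f]]) for f in self.factor_names}
        return float(self.predict_columns(cols)[0])

    def coefficients_natural(self) -> dict[str, float]:
        """Expand coded coefficients into natural-unit polynomial weights.

        Keys are term labels over natural factors ('1', 'x', 'x*y', 'x^2').
        """
        acc: dict[tuple, float] = {}

        def add(monomial: tuple, w: float) -> None:
            acc[monomial] = acc.get(monomial, 0.0) + w

        for term, beta in self.coefficients.items():
            if term.kind == "intercept":
                add((), beta)
                continue
            # each coded factor is (x - mid)/half: a linear polynomial
            polys = []
            for f in term.factors:
                mid, half = self.coding[f]
                polys.append({(): -mid / half, (f,): 1.0 / half})
            if term.kind == "quadratic":
                polys.append(dict(polys[0]))
            prod: dict[tuple, float] = {(): 1.0}
            for poly in polys:
                nxt: dict[tuple, float] = {}
                for m1, w1 in prod.items():
                    for m2, w2 in poly.items():
                        m = tuple(sorted(m1 + m2))
                        nxt[m] = nxt.get(m, 0.0) + w1 * w2
                prod = nxt
            for m, w in prod.items():
                add(m, beta * w)

        def label(m: tuple) -> str:
            if not m:
                return "1"
            if len(m) == 1:
                return m[0]
            if m[0] == m[1]:
                return f"{m[0]}^2"
            return f"{m[0]}*{m[1]}"

        return {label(m): w for m, w in sorted(acc.items())}

    def summary(self) -> dict:
        return {
            "terms": [t.label() for t in self.terms],
            "coefficients_coded": {
                t.label(): self.coefficients[t] for t in self.terms
            },
            "coefficients_natural": self.coefficients_natural(),
            "r2": self.r2,
            "q2": self.q2,
            "n_runs": self.n_runs,
        }


def fit_and_validate(
    rows: Sequence[Mapping[str, float]],
    responses: Sequence[float],
    terms: Iterable[Term],
    coding: Mapping[str, tuple[float, float]] | None = None,
) -> SurrogateModel:
    """Least-squares fit with R2 and leave-one-out Q2.

    ``rows`` hold concrete (natural-unit) settings of the numeric factors;
    they are normalized to coded [-1, 1] internally (from the data range
    unless an explicit ``coding`` is given).
    """
    terms = normalize_terms(terms)
    factor_names = tuple(
        sorted({f for t in terms for f in t.factors})
    )
    y = np.asarray(list(responses), dtype=float)
    n, p = len(rows), len(terms)
    if len(y) != n:
        raise ValidationError("responses and design rows differ in length")
    if n <= p:
        raise ValidationError(
            f"need more runs ({n}) than model terms ({p})"
        )
    if coding is None:
        all_names = tuple(sorted(rows[0])) if rows else ()
        coding = _coding_from_rows(rows, all_names or factor_names)
    natural = {f: np.array([float(r[f]) for r in rows]) for f in coding}
    coded = _code(natural, coding)
    X = np.column_stack([_term_column(t, coded) for t in terms])
    if np.linalg.matrix_rank(X) < p:
        raise FitError(
            "rank-deficient term matrix; collinear terms among: "
            + ", ".join(t.label() for t in terms)
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    # exact LOO residuals: e_i / (1 - h_ii)
    xtx = X.T @ X
    hat = np.einsum("ij,ij->i", X, np.linalg.solve(xtx, X.T).T)
    leverage_ok = hat < 1.0 - 1e-10
    if sst <= 0.0:
        r2 = 1.0 if sse <= 1e-300 else -math.inf
        q2 = -math.inf
    else:
        r2 = 1.0 - sse / sst
        if not leverage_ok.all():
            q2 = -math.inf
        else:
            press = float(((resid / (1.0 - hat)) ** 2).sum())
            q2 = 1.0 - press / sst
    return SurrogateModel(
        terms=terms,
        coefficients={t: float(b) for t, b in zip(terms, beta)},
        r2=r2,
        q2=q2,
        n_runs=n,
        coding=dict(coding),
        factor_names=tuple(sorted(coding)),
    )


def select_model(
    rows: Sequence[Mapping[str, float]],
    responses: Sequence[float],
    method: str = "best_subset",
    candidates: Sequence[Term] | None = None,
    max_best_subset_candidates: int = 20,
) -> SurrogateModel:
    """Choose a term set by maximizing leave-one-out Q2.

    ``best_subset`` searches every subset of the candidate terms (intercept
    forced); ties prefer fewer terms, then the lexicographically smallest
    term set.  ``greedy_forward`` starts from the intercept-only model and
    adds the single term with the largest Q2 gain until no addition improves.
    """
    if candidates is None:
        factor_names = sorted(rows[0]) if rows else []
        candidates = candidate_terms(factor_names)
    cands = sorted(
        {t for t in candidates if t.kind != "intercept"},
        key=lambda t: t.sort_key,
    )
    coding = _coding_from_rows(rows, sorted(rows[0])) if rows else {}

    def try_fit(terms):
        try:
            return fit_and_validate(rows, responses, terms, coding=coding)
        except (FitError, ValidationError):
            return None

    if method == "best_subset":
        if len(cands) > max_best_subset_candidates:
            raise ValidationError(
                f"best_subset limited to {max_best_subset_candidates} "
                f"candidate terms (got {len(cands)}); use greedy_forward"
            )
        best = None
        best_key = None
        for r in range(len(cands) + 1):
            for combo in itertools.combinations(cands, r):
                model = try_fit(combo)
                if model is None:
                    continue
                key = (
                    -model.q2,
                    len(model.terms),
                    tuple(t.sort_key for t in model.terms),
                )
                if best_key is None or key < best_key:
                    best, best_key = model, key
        if best is None:
            raise SelectionError("no candidate model could be fitted")
        return best

    if method == "greedy_forward":
        current: list[Term] = []
        best = try_fit(current)
        if best is None:
            raise SelectionError("intercept-only model could not be fitted")
        while True:
            improvement = None
            for t in cands:
                if t in current:
                    continue
                model = try_fit(current + [t])
                if model is None:
                    continue
                if model.q2 > best.q2 and (
                    improvement is None or model.q2 > improvement[0].q2
                ):
                    improvement = (model, t)
            if improvement is None:
                return best
            best, added = improvement
            current.append(added)

    raise ValidationError(f"unknown model-selection method {method!r}")


@dataclass(frozen=True)
class PredictedOptimum:
    configuration: dict
    predicted_value: float
    at_region_boundary: dict = field(default_factory=dict)


#: memory guard for the dense prediction grid
MAX_GRID_POINTS = 3_000_000


def _axis(low, high, is_ordinal, n_grid):
    if is_ordinal:
        lo, hi = math.ceil(low - 1e-9), math.floor(high + 1e-9)
        if hi < lo:
            lo = hi = int(round((low + high) / 2.0))
        if hi - lo + 1 <= n_grid:
            return np.arange(lo, hi + 1, dtype=float)
        pts = np.unique(np.round(np.linspace(lo, hi, n_grid)))
        return pts.astype(float)
    return np.linspace(low, high, n_grid)


def predict_optimum(
    models: SurrogateModel | Mapping[str, SurrogateModel],
    region: Mapping[str, tuple[float, float]],
    ordinal_factors: Iterable[str] = (),
    goal: str = MAXIMIZE,
    specs: Sequence[ResponseSpec] | None = None,
    n_grid: int = 51,
) -> PredictedOptimum:
    """Locate the model optimum inside ``region`` by dense grid search.

    Single model: optimize the predicted response under ``goal``.  Several
    models plus their response specs: maximize the geometric-mean
    desirability of the per-response predictions.  Ties prefer the
    configuration closest to the region center (Euclidean in coded units),
    then the lexicographically smallest grid point.
    """
    names = sorted(region)
    for f in names:
        low, high = region[f]
        if not (low < high):
            raise ValidationError(f"factor {f!r}: degenerate region [{low}, {high}]")
    if goal not in (MAXIMIZE, MINIMIZE):
        raise ValidationError(f"goal must be maximize or minimize (got {goal!r})")
    ordinal_factors = set(ordinal_factors)

    k = len(names)
    grid_n = n_grid
    while grid_n > 5 and grid_n**k > MAX_GRID_POINTS:
        grid_n -= 2
    axes = [
        _axis(*region[f], f in ordinal_factors, grid_n) for f in names
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    cols = {f: m.ravel() for f, m in zip(names, mesh)}

    if isinstance(models, SurrogateModel):
        pred = models.predict_columns(cols)
        objective = pred if goal == MAXIMIZE else -pred
        reported = pred
    else:
        if specs is None or len(specs) != len(models):
            raise ValidationError(
                "multi-model prediction needs one ResponseSpec per model"
            )
        spec_by_name = {s.name: s for s in specs}
        des = []
        for name, model in models.items():
            des.append(
                desirability_array(model.predict_columns(cols), spec_by_name[name])
            )
        stack = np.vstack(des)
        with np.errstate(divide="ignore"):
            objective = np.exp(np.log(stack).mean(axis=0))
        objective[np.isnan(objective)] = 0.0
        reported = objective

    best_val = objective.max()
    tied = np.flatnonzero(objective == best_val)
    centers = np.array([(region[f][0] + region[f][1]) / 2.0 for f in names])
    halves = np.array([(region[f][1] - region[f][0]) / 2.0 for f in names])
    pts = np.column_stack([cols[f][tied] for f in names])
    dist = (((pts - centers) / halves) ** 2).sum(axis=1)
    idx = tied[int(np.argmin(dist))]

    config = {}
    boundary = {}
    for f in names:
        v = float(cols[f][idx])
        if f in ordinal_factors:
            v = int(round(v))
        config[f] = v
        low, high = region[f]
        tol = 1e-9 * max(1.0, abs(high - low))
        boundary[f] = bool(v <= low + tol or v >= high - tol)
    return PredictedOptimum(config, float(reported[idx]), boundary)
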