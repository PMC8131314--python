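"""Idiographic dynamic networks: covariate adjustment, lag-1 models of up
to three variables, standardized lagged and contemporaneous estimates, and
the relevance filter.

The estimator is a transparent two-step frequentist procedure:

1. each variable is detrended (low-pass trend) and adjusted for
   time-of-day slot means and a weekend offset by least squares;
2. per-equation OLS regresses each variable's adjusted residual at
   occasion t on all model variables' residuals at t-1 over eligible lag
   pairs (same-day consecutive prompts, all variables observed at both
   occasions; an overnight gap is never one lag).  Contemporaneous
   structure is the (partial) correlation of the lagged-model innovations.

Coefficients are standardized by the ratio of within-person residual SDs,
so a lagged edge is in SD-per-SD units — comparable across variables and
against the relevance threshold (default |beta| > 0.2 with p < 0.05,
strict inequalities).  Lagged edges carry Granger-style direction
(source at t-1 -> target at t): they suggest, but do not prove, causation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .basic_report import GriddedSeries, TrendDecomposition, lowpass_trend, to_equidistant_grid
from .errors import (
    CollinearityError,
    InsufficientDataError,
    ParameterError,
    UnknownVariableError,
)
from .synthetic_cohort import EmaDataset

__all__ = [
    "AdjustedSeries",
    "LagPair",
    "LaggedEdge",
    "ContemporaneousEdge",
    "NetworkModel",
    "RelevanceCriteria",
    "covariate_adjust",
    "build_lag_pairs",
    "fit_lagged_model",
    "fit_contemporaneous",
    "relevance_filter",
    "enumerate_models",
    "estimate_network",
    "MAX_MODEL_VARIABLES",
]

MAX_MODEL_VARIABLES = 3
CONDITION_NUMBER_GUARD = 1e6


@dataclass(frozen=True)
class AdjustedSeries:
    """Residuals after removing trend, time-of-day and weekend components.

    The removed parts are stored so observed = residual + trend +
    slot effect + weekend effect at every non-missing occasion.
    """

    variable: str
    residual: np.ndarray
    removed_trend: np.ndarray
    removed_slot: np.ndarray
    removed_weekend: np.ndarray
    slot_effects: dict[int, float]
    weekend_offset: float
    residual_sd: float
    day_index: np.ndarray
    slot_of_day: np.ndarray
    per_day_count: int
    flags: tuple[str, ...] = ()

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.residual)


class LagPair(NamedTuple):
    """Occasion indices (t-1, t) eligible for lagged modelling."""

    prev: int
    curr: int


@dataclass(frozen=True)
class LaggedEdge:
    source: str
    target: str
    beta: float  # standardized
    se: float
    p: float

    @property
    def is_self(self) -> bool:
        return self.source == self.target

    def key(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class ContemporaneousEdge:
    a: str
    b: str
    r: float  # (partial) correlation of innovations
    p: float

    def key(self) -> str:
        return "~".join(sorted((self.a, self.b)))


@dataclass(frozen=True)
class RelevanceCriteria:
    """Edge-retention rule: significant (p < alpha) AND sizeable
    (|standardized estimate| > beta_min), both strict."""

    alpha: float = 0.05
    beta_min: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.beta_min < 0:
            raise ParameterError(f"beta_min must be >= 0, got {self.beta_min}")

    def keeps(self, estimate: float, p: float) -> bool:
        return p < self.alpha and abs(estimate) > self.beta_min


@dataclass(frozen=True)
class NetworkModel:
    variables: tuple[str, ...]
    lagged_edges: tuple[LaggedEdge, ...]
    contemporaneous_edges: tuple[ContemporaneousEdge, ...]
    n_lag_pairs: int
    n_occasions_used: int
    innovations: np.ndarray | None = field(default=None, repr=False, compare=False)
    filtered: bool = False

    def cross_lagged_edges(self) -> tuple[LaggedEdge, ...]:
        """Between-variable lagged edges (the network edges a report shows;
        autoregressive self-effects stay in the technical appendix)."""
        return tuple(e for e in self.lagged_edges if not e.is_self)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "n_lag_pairs": self.n_lag_pairs,
            "n_occasions_used": self.n_occasions_used,
            "filtered": self.filtered,
            "edges": [
                {
                    "type": "lagged",
                    "source": e.source,
                    "target": e.target,
                    "estimate": e.beta,
                    "se": e.se,
                    "p": e.p,
                    "sign": "positive" if e.beta >= 0 else "negative",
                }
                for e in self.lagged_edges
            ]
            + [
                {
                    "type": "contemporaneous",
                    "a": e.a,
                    "b": e.b,
                    "estimate": e.r,
                    "p": e.p,
                    "sign": "positive" if e.r >= 0 else "negative",
                }
                for e in self.contemporaneous_edges
            ],
        }

    def to_dot(self, name: str = "network") -> str:
        """Graphviz DOT; positive edges black, negative red (the report's
        display convention), contemporaneous edges dashed and undirected."""
        lines = [f"digraph {name} {{", "  rankdir=LR;", "  node [shape=ellipse];"]
        for v in self.variables:
            lines.append(f'  "{v}";')
        for e in self.lagged_edges:
            color = "black" if e.beta >= 0 else "red"
            lines.append(
                f'  "{e.source}" -> "{e.target}" [color={color}, '
                f'label="{e.beta:+.2f}"];'
            )
        for e in self.contemporaneous_edges:
            color = "black" if e.r >= 0 else "red"
            lines.append(
                f'  "{e.a}" -> "{e.b}" [dir=none, style=dashed, color={color}, '
                f'label="{e.r:+.2f}"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"


def covariate_adjust(series: GriddedSeries, trend: TrendDecomposition) -> AdjustedSeries:
    """Remove trend, then least-squares time-of-day slot means and a
    weekend offset, estimated jointly on the detrended series.

    Slots with no observations get a zero effect and a warning flag; if the
    weekend indicator is degenerate (all or no observed occasions fall on a
    weekend) its offset is fixed at zero with a flag.
    """
    if len(trend.trend) != len(series):
        raise ParameterError("trend decomposition was computed on a different grid")
    detrended = series.values - trend.trend
    obs = ~np.isnan(detrended)
    flags: list[str] = []
    n_slots = series.per_day_count
    slot = series.slot_of_day
    wknd = series.is_weekend.astype(float)

    slot_effects = np.zeros(n_slots)
    weekend_offset = 0.0
    if obs.any():
        use_weekend = 0 < wknd[obs].sum() < obs.sum()
        if not use_weekend:
            flags.append("weekend-degenerate")
        cols = n_slots + (1 if use_weekend else 0)
        x = np.zeros((int(obs.sum()), cols))
        x[np.arange(obs.sum()), slot[obs]] = 1.0
        if use_weekend:
            x[:, -1] = wknd[obs]
        seen = np.unique(slot[obs])
        if len(seen) < n_slots:
            flags.append("empty-slot")
        coef, *_ = np.linalg.lstsq(x, detrended[obs], rcond=None)
        slot_effects[seen] = coef[seen]
        if use_weekend:
            weekend_offset = float(coef[-1])
    else:
        flags.append("all-missing")

    removed_slot = slot_effects[slot].astype(float)
    removed_weekend = weekend_offset * wknd
    residual = detrended - removed_slot - removed_weekend
    sd = float(np.nanstd(residual, ddof=1)) if obs.sum() > 1 else float("nan")
    return AdjustedSeries(
        variable=series.variable,
        residual=residual,
        removed_trend=trend.trend,
        removed_slot=removed_slot,
        removed_weekend=removed_weekend,
        slot_effects={int(series.clock_minutes[series.slot_of_day == s][0]): float(slot_effects[s])
                      for s in range(n_slots)},
        weekend_offset=weekend_offset,
        residual_sd=sd,
        day_index=series.day_index,
        slot_of_day=series.slot_of_day,
        per_day_count=series.per_day_count,
        flags=tuple(flags),
    )


def build_lag_pairs(adjusted: list[AdjustedSeries]) -> list[LagPair]:
    """(t-1, t) pairs of consecutive same-day prompts with every model
    variable observed at both occasions.  Overnight gaps never pair."""
    if not adjusted:
        raise ParameterError("need at least one adjusted series")
    n = len(adjusted[0].residual)
    if n < 2:
        raise InsufficientDataError("need at least 2 occasions to form lag pairs")
    day = adjusted[0].day_index
    slot = adjusted[0].slot_of_day
    all_obs = np.ones(n, dtype=bool)
    for a in adjusted:
        if len(a.residual) != n:
            raise ParameterError("adjusted series are on different grids")
        all_obs &= a.observed
    pairs = [
        LagPair(t - 1, t)
        for t in range(1, n)
        if day[t] == day[t - 1]
        and slot[t] == slot[t - 1] + 1
        and all_obs[t]
        and all_obs[t - 1]
    ]
    return pairs


def _standardized_design(adjusted: list[AdjustedSeries], pairs: list[LagPair]):
    prev = np.array([p.prev for p in pairs], dtype=int)
    curr = np.array([p.curr for p in pairs], dtype=int)
    rstd = np.column_stack([a.residual / a.residual_sd for a in adjusted])
    return rstd[prev], rstd[curr]


def fit_lagged_model(
    adjusted: list[AdjustedSeries],
    pairs: list[LagPair],
    min_pairs_per_predictor: int = 10,
) -> NetworkModel:
    """Per-equation OLS of each target's standardized residual at t on all
    model variables' standardized residuals at t-1.

    Because predictors and targets are standardized by their within-person
    residual SDs before the fit, the reported coefficients are standardized
    betas.  Two-sided p-values come from the OLS t-tests.
    """
    k = len(adjusted)
    if k < 2:
        raise ParameterError("a lagged model needs at least 2 variables")
    if k > MAX_MODEL_VARIABLES:
        raise ParameterError(
            f"at most {MAX_MODEL_VARIABLES} variables per model, got {k}"
        )
    n = len(pairs)
    needed = min_pairs_per_predictor * k
    if n < needed:
        raise InsufficientDataError(
            f"{n} lag pairs available but at least {needed} required "
            f"({min_pairs_per_predictor} per lagged predictor)"
        )
    x_prev, y_curr = _standardized_design(adjusted, pairs)
    x = sm.add_constant(x_prev, has_constant="add")
    if np.linalg.cond(x) > CONDITION_NUMBER_GUARD:
        raise CollinearityError(
            f"lagged predictors are collinear (condition number > {CONDITION_NUMBER_GUARD:g})"
        )
    names = [a.variable for a in adjusted]
    edges = []
    innov = np.empty_like(y_curr)
    for j, target in enumerate(names):
        fit = sm.OLS(y_curr[:, j], x).fit()
        innov[:, j] = fit.resid
        for i, source in enumerate(names):
            edges.append(
                LaggedEdge(
                    source=source,
                    target=target,
                    beta=float(fit.params[i + 1]),
                    se=float(fit.bse[i + 1]),
                    p=float(fit.pvalues[i + 1]),
                )
            )
    occasions = {p.prev for p in pairs} | {p.curr for p in pairs}
    return NetworkModel(
        variables=tuple(names),
        lagged_edges=tuple(edges),
        contemporaneous_edges=(),
        n_lag_pairs=n,
        n_occasions_used=len(occasions),
        innovations=innov,
    )


def _fisher_p(r: float, n_eff: int) -> float:
    """Two-sided p for a correlation via the Fisher normalizing transform;
    ``n_eff`` is the innovation sample size minus conditioning covariates."""
    if n_eff <= 3:
        return 1.0
    r = float(np.clip(r, -0.999999, 0.999999))
    z = np.arctanh(r) * np.sqrt(n_eff - 3)
    return float(2 * stats.norm.sf(abs(z)))


def fit_contemporaneous(model: NetworkModel, min_occasions: int = 30) -> NetworkModel:
    """Partial correlations of the lagged-model innovations.

    With two variables this is the plain innovation correlation; with
    three, each pair is partialled on the remaining variable.  The Fisher-z
    sample size is reduced by the number of conditioning covariates (the K
    lagged predictors, plus the partialled third variable).
    """
    if model.innovations is None:
        raise ParameterError("model carries no innovations; fit the lagged model first")
    innov = model.innovations
    n, k = innov.shape
    if n < min_occasions:
        raise InsufficientDataError(
            f"{n} co-observed occasions available but at least {min_occasions} required"
        )
    names = model.variables
    edges = []
    if k == 2:
        r = float(np.corrcoef(innov[:, 0], innov[:, 1])[0, 1])
        edges.append(
            ContemporaneousEdge(names[0], names[1], r, _fisher_p(r, n - k))
        )
    else:
        prec = np.linalg.inv(np.cov(innov, rowvar=False))
        for i, j in itertools.combinations(range(k), 2):
            r = float(-prec[i, j] / np.sqrt(prec[i, i] * prec[j, j]))
            # one extra conditioning variable per partialled-out column
            edges.append(
                ContemporaneousEdge(names[i], names[j], r, _fisher_p(r, n - k - (k - 2)))
            )
    return replace(model, contemporaneous_edges=tuple(edges))


def relevance_filter(
    model: NetworkModel,
    criteria: RelevanceCriteria | None = None,
    manual_drop: set[str] | frozenset[str] | None = None,
) -> NetworkModel:
    """Keep edges with p < alpha and |estimate| > beta_min (strict).

    ``manual_drop`` holds edge keys ("source->target" for lagged,
    "a~b" sorted for contemporaneous) for the clinical-relevance step:
    curation can only remove statistically passing edges, never add.
    Idempotent; output edges are always a subset of input edges.
    """
    criteria = criteria or RelevanceCriteria()
    drop = set(manual_drop or ())
    lagged = tuple(
        e
        for e in model.lagged_edges
        if criteria.keeps(e.beta, e.p) and e.key() not in drop
    )
    contemp = tuple(
        e
        for e in model.contemporaneous_edges
        if criteria.keeps(e.r, e.p) and e.key() not in drop
    )
    return replace(model, lagged_edges=lagged, contemporaneous_edges=contemp, filtered=True)


def enumerate_models(
    variables: list[str], focal: str, max_vars: int = MAX_MODEL_VARIABLES
) -> list[tuple[str, ...]]:
    """All subsets of 2..max_vars variables containing the focal variable,
    in deterministic order (by size, then by position in ``variables``)."""
    if focal not in variables:
        raise UnknownVariableError(f"focal variable {focal!r} not among {list(variables)}")
    others = [v for v in variables if v != focal]
    out: list[tuple[str, ...]] = []
    for size in range(2, max_vars + 1):
        for combo in itertools.combinations(others, size - 1):
            subset = tuple(v for v in variables if v == focal or v in combo)
            out.append(subset)
    return out


def estimate_network(
    dataset: EmaDataset,
    variables: list[str] | tuple[str, ...],
    window_days: float = 3.0,
    min_pairs_per_predictor: int = 10,
    min_occasions: int = 30,
) -> NetworkModel:
    """Full single-model pipeline: grid -> trend -> adjust -> lag pairs ->
    lagged fit -> contemporaneous fit."""
    adjusted = []
    for v in variables:
        series = to_equidistant_grid(dataset, v)
        trend = lowpass_trend(series, window_days=window_days)
        adjusted.append(covariate_adjust(series, trend))
    pairs = build_lag_pairs(adjusted)
    model = fit_lagged_model(adjusted, pairs, min_pairs_per_predictor=min_pairs_per_predictor)
    return fit_contemporaneous(model, min_occasions=min_occasions)
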