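"""Composite indices: HDI, national HDI shares, and pollution-control effectiveness.

The Human Development Index is the geometric mean of three dimension indices
(health, education, income), each rescaled to [0, 1] by fixed goalposts; the
income dimension is log-scaled after conversion to international dollars at
purchasing-power parity.  Pollution-control effectiveness inverts and
log-standardizes a basket of emission indicators onto [0.6, 1.0] (higher =
less pollution) and aggregates them by a weight vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    RangeError,
)

logger = logging.getLogger(__name__)

#: Default PPP conversion factor (local currency units per international
#: dollar, 2017 round for China).
DEFAULT_PPP = 4.184


@dataclass(frozen=True)
class Goalposts:
    """Fixed scaling anchors for the three HDI dimensions.

    Defaults follow the HDR-2020 technical-note goalposts: life expectancy
    20-85 years, income 100-75,000 international dollars (log scale), and a
    maximum of 16 effective schooling years with attainment levels (primary,
    junior secondary, senior secondary, tertiary) mapped to (6, 9, 12, 16)
    years.
    """

    health_min: float = 20.0
    health_max: float = 85.0
    income_min: float = 100.0
    income_max: float = 75_000.0
    education_max: float = 16.0
    schooling_coefficients: tuple[float, ...] = (6.0, 9.0, 12.0, 16.0)
    ppp_factor: float = DEFAULT_PPP

    def __post_init__(self) -> None:
        if not (self.health_min < self.health_max):
            raise ConfigurationError("health goalposts must satisfy min < max")
        if not (0 < self.income_min < self.income_max):
            raise ConfigurationError("income goalposts must satisfy 0 < min < max")
        if self.education_max <= 0:
            raise ConfigurationError("education_max must be positive")
        if self.ppp_factor <= 0:
            raise ConfigurationError("ppp_factor must be positive")
        coeffs = self.schooling_coefficients
        if any(b < a for a, b in zip(coeffs, coeffs[1:])):
            raise ConfigurationError("schooling coefficients must be nondecreasing")


@dataclass(frozen=True)
class HDIComponents:
    """The three dimension indices, each already scaled to [0, 1]."""

    i_health: float
    i_education: float
    i_income: float

    def __post_init__(self) -> None:
        for name in ("i_health", "i_education", "i_income"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class StandardizationContext:
    """Pooled extrema of one negative indicator, fixing the [0.6, 1] map."""

    indicator_name: str
    x_max: float
    x_min: float
    pooling_scope: str = "window"  # "window" | "full-period"

    def __post_init__(self) -> None:
        if not (0 < self.x_min <= self.x_max):
            raise ConfigurationError(
                f"{self.indicator_name}: need 0 < x_min <= x_max, "
                f"got ({self.x_min}, {self.x_max})"
            )


def dimension_index(value: float, lo: float, hi: float, log_scale: bool = False) -> float:
    """Rescale a raw measurement onto [0, 1] between goalposts.

    With ``log_scale`` the rescaling happens in log space, which is the HDI
    convention for income (diminishing returns to material welfare).
    The result is clamped to [0, 1].
    """
    if hi <= lo:
        raise ConfigurationError(f"goalposts must satisfy hi > lo, got ({lo}, {hi})")
    if log_scale:
        if value <= 0 or lo <= 0 or hi <= 0:
            raise DomainError("log-scaled dimension requires strictly positive inputs")
        raw = (math.log(value) - math.log(lo)) / (math.log(hi) - math.log(lo))
    else:
        raw = (value - lo) / (hi - lo)
    return min(1.0, max(0.0, raw))


def income_index(gni_pc_local: float, gp: Goalposts) -> float:
    """Income dimension: convert to international dollars, then log-rescale."""
    if gni_pc_local <= 0:
        raise DomainError(f"per-capita income must be positive, got {gni_pc_local}")
    gni_ppp = gni_pc_local / gp.ppp_factor
    return dimension_index(gni_ppp, gp.income_min, gp.income_max, log_scale=True)


def education_index(attainment_proportions: Sequence[float], gp: Goalposts) -> float:
    """Education dimension from population shares by attainment level.

    Mean schooling years are the attainment shares weighted by the schooling
    coefficients; the index divides by the education goalpost.
    """
    props = list(attainment_proportions)
    if len(props) != len(gp.schooling_coefficients):
        raise ConfigurationError(
            f"expected {len(gp.schooling_coefficients)} attainment proportions, "
            f"got {len(props)}"
        )
    if any(p < 0 for p in props):
        raise DomainError("attainment proportions must be nonnegative")
    if any(p > 1 for p in props) or sum(props) > 1 + 1e-9:
        raise DomainError("attainment proportions must lie in [0,1] and sum to <= 1")
    mean_years = sum(c * p for c, p in zip(gp.schooling_coefficients, props))
    return min(1.0, max(0.0, mean_years / gp.education_max))


def compute_hdi(c: HDIComponents) -> float:
    """Geometric mean of the three dimension indices."""
    return (c.i_health * c.i_education * c.i_income) ** (1.0 / 3.0)


def hdi_share(hdi_by_entity: Mapping[str, float]) -> dict[str, float]:
    """One entity's HDI over the sum of all entities' HDIs (single year).

    The share series is the H(t) input of the coupling model: it tracks the
    *relative* pace of development rather than the level.
    """
    total = float(sum(hdi_by_entity.values()))
    if total <= 0:
        raise DegenerateInputError("all HDI values are zero; shares undefined")
    if any(v < 0 for v in hdi_by_entity.values()):
        raise DomainError("HDI values must be nonnegative")
    return {k: v / total for k, v in hdi_by_entity.items()}


def interpolate_linear(series: Mapping[int, float] | pd.Series,
                       years: Iterable[int]) -> pd.Series:
    """Fill missing years of an annual series.

    Interior gaps (census-year-only life expectancy, typically) are filled by
    straight-line interpolation between the nearest observed anchors; years
    outside the observed span are extended with the nearest anchor's value
    rather than extrapolated, to avoid implausible tail values.
    """
    s = pd.Series(dict(series) if not isinstance(series, pd.Series) else series,
                  dtype=float).sort_index()
    s = s.dropna()
    if len(s) < 2:
        raise InsufficientDataError(
            f"need at least two observed anchors, got {len(s)}"
        )
    target = pd.Index(sorted(set(int(y) for y in years) | set(s.index)))
    out = s.reindex(target).interpolate(method="index", limit_area="inside")
    n_exterior = int(out.isna().sum())
    if n_exterior:
        logger.info("extending %d exterior year(s) with nearest anchor", n_exterior)
        out = out.ffill().bfill()
    return out.loc[sorted(set(int(y) for y in years))]


def make_context(values: Iterable[float], indicator_name: str,
                 pooling_scope: str = "window") -> StandardizationContext:
    """Pool an indicator's values into a standardization context.

    Non-positive observations break the logarithm in the negative-indicator
    map; they are floored at the smallest positive observed value of the
    indicator (with a warning), mirroring how near-zero emission series such
    as an island province's SO2 are handled.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or not np.isfinite(arr).all():
        raise DomainError(f"{indicator_name}: empty or non-finite values")
    positive = arr[arr > 0]
    if positive.size == 0:
        raise DomainError(f"{indicator_name}: no positive values to standardize")
    if positive.size < arr.size:
        logger.warning(
            "%s: %d non-positive value(s) floored at %g",
            indicator_name, arr.size - positive.size, positive.min(),
        )
    return StandardizationContext(
        indicator_name=indicator_name,
        x_max=float(positive.max()),
        x_min=float(positive.min()),
        pooling_scope=pooling_scope,
    )


def floor_positive(x: float, ctx: StandardizationContext) -> float:
    """Floor a non-positive observation at the pooled minimum."""
    return x if x > 0 else ctx.x_min


def standardize_negative(x: float, ctx: StandardizationContext) -> float:
    """Map a negative (bad-when-large) indicator onto [0.6, 1.0].

    score = 0.6 + 0.4 * (ln x_max - ln x) / (ln x_max - ln x_min)

    The pooled maximum maps to exactly 0.6, the pooled minimum to exactly
    1.0, and the map is strictly decreasing in between.  A degenerate
    indicator (x_max == x_min) returns 1.0 by convention.
    """
    x = floor_positive(x, ctx)
    if not (ctx.x_min <= x <= ctx.x_max):
        raise RangeError(
            f"{ctx.indicator_name}: {x} outside pooled range "
            f"[{ctx.x_min}, {ctx.x_max}]"
        )
    if ctx.x_max == ctx.x_min:
        logger.warning("%s: degenerate pooled range, returning 1.0",
                       ctx.indicator_name)
        return 1.0
    span = math.log(ctx.x_max) - math.log(ctx.x_min)
    return 0.6 + 0.4 * (math.log(ctx.x_max) - math.log(x)) / span


def effectiveness_index(scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted aggregate of standardized pollution scores.

    Because each score lies in [0.6, 1.0] and the weights form a convex
    combination, the aggregate stays in [0.6, 1.0]; higher means less
    pollution relative to the pooled scope.
    """
    if len(scores) != len(weights):
        raise ConfigurationError(
            f"{len(scores)} scores but {len(weights)} weights"
        )
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ConfigurationError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"weights must sum to 1, got {w.sum()}")
    return float(np.dot(np.asarray(scores, dtype=float), w))


def merge_vehicle_emissions(domestic_series: pd.Series,
                            vehicle_series: pd.Series) -> pd.Series:
    """Add motor-vehicle emissions onto a domestic emission series.

    Both series must be indexed by identical (entity, year) keys; the sum
    replaces the original domestic series for NOx and soot, where household
    statistics omit the vehicle fleet.
    """
    d_idx, v_idx = set(domestic_series.index), set(vehicle_series.index)
    if d_idx != v_idx:
        missing = sorted(d_idx ^ v_idx)[:5]
        raise AlignmentError(
            f"domestic and vehicle series keys differ (e.g. {missing})"
        )
    return domestic_series + vehicle_series.reindex(domestic_series.index)


# ---------------------------------------------------------------------------
# Panel-level drivers (long format: entity, year, indicator, value)
# ---------------------------------------------------------------------------

#: Indicator names the synthetic panel and the pipeline agree on.
HDI_HEALTH = "life_expectancy"
HDI_EDU_LEVELS = ("edu_primary", "edu_junior", "edu_senior", "edu_college")
HDI_INCOME = "gni_per_capita"

INDUSTRIAL_INDICATORS = (
    "ind_cod", "ind_nh3n", "ind_so2", "ind_nox", "ind_smoke_dust",
    "ind_solid_waste",
)
DOMESTIC_INDICATORS = (
    "dom_cod", "dom_nh3n", "dom_so2", "dom_nox", "dom_smoke_dust",
    "dom_garbage",
)
#: domestic indicator -> vehicle indicator merged into it
VEHICLE_MERGE = {"dom_nox": "veh_nox", "dom_smoke_dust": "veh_smoke_dust"}


def _pivot(panel: pd.DataFrame, indicator: str) -> pd.DataFrame:
    sub = panel[panel["indicator"] == indicator]
    return sub.pivot(index="year", columns="entity", values="value")


def compute_hdi_panel(panel: pd.DataFrame, gp: Goalposts | None = None,
                      years: Sequence[int] | None = None) -> pd.DataFrame:
    """HDI per entity and year from a long indicator panel.

    Life expectancy gaps are filled by linear interpolation; education and
    income series are expected complete.  Returns a year x entity frame.
    """
    gp = gp or Goalposts()
    if years is None:
        years = sorted(panel["year"].unique())
    entities = sorted(panel["entity"].unique())
    life = _pivot(panel, HDI_HEALTH)
    edu = {lvl: _pivot(panel, lvl) for lvl in HDI_EDU_LEVELS}
    income = _pivot(panel, HDI_INCOME)

    out = pd.DataFrame(index=list(years), columns=entities, dtype=float)
    for e in entities:
        life_e = interpolate_linear(life[e].dropna(), years)
        for y in years:
            i_h = dimension_index(life_e.loc[y], gp.health_min, gp.health_max)
            props = [edu[lvl].loc[y, e] for lvl in HDI_EDU_LEVELS]
            i_e = education_index(props, gp)
            i_i = income_index(income.loc[y, e], gp)
            out.loc[y, e] = compute_hdi(HDIComponents(i_h, i_e, i_i))
    out.index.name = "year"
    out.columns.name = "entity"
    return out


def hdi_share_panel(hdi: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a year x entity HDI frame into national shares."""
    shares = hdi.apply(lambda row: pd.Series(hdi_share(row.to_dict())), axis=1)
    return shares[hdi.columns]


def effectiveness_panel(panel: pd.DataFrame, indicators: Sequence[str],
                        weights: Sequence[float] | None = None,
                        years: Sequence[int] | None = None,
                        pooling_scope: str = "window") -> pd.DataFrame:
    """Effectiveness index per entity and year for one pollution basket.

    Extrema are pooled over all entities and all ``years`` (one analysis
    window, or the full period).  ``weights`` defaults to equal 1/k.
    Vehicle-emission merging must already have been applied to the panel
    (see :func:`apply_vehicle_merge`).
    """
    if weights is None:
        weights = [1.0 / len(indicators)] * len(indicators)
    if len(weights) != len(indicators):
        raise ConfigurationError("one weight per indicator required")
    if years is None:
        years = sorted(panel["year"].unique())
    years = list(years)
    sub = panel[panel["year"].isin(years)]
    wide = {ind: _pivot(sub, ind) for ind in indicators}
    ctxs = {
        ind: make_context(wide[ind].to_numpy().ravel(), ind, pooling_scope)
        for ind in indicators
    }
    entities = sorted(sub["entity"].unique())
    out = pd.DataFrame(index=years, columns=entities, dtype=float)
    for e in entities:
        for y in years:
            scores = [standardize_negative(wide[ind].loc[y, e], ctxs[ind])
                      for ind in indicators]
            out.loc[y, e] = effectiveness_index(scores, weights)
    out.index.name = "year"
    out.columns.name = "entity"
    return out


def apply_vehicle_merge(panel: pd.DataFrame,
                        merge_map: Mapping[str, str] = VEHICLE_MERGE) -> pd.DataFrame:
    """Fold motor-vehicle emission rows into their domestic counterparts.

    Returns a new panel where each domestic indicator in ``merge_map`` has
    been replaced by its element-wise sum with the matching vehicle series;
    vehicle rows are dropped.
    """
    panel = panel.copy()
    for dom, veh in merge_map.items():
        d = panel[panel["indicator"] == dom].set_index(["entity", "year"])["value"]
        v = panel[panel["indicator"] == veh].set_index(["entity", "year"])["value"]
        if d.empty or v.empty:
            continue
        merged = merge_vehicle_emissions(d, v)
        mask = panel["indicator"] == dom
        keyed = panel.loc[mask].set_index(["entity", "year"]).index
        panel.loc[mask, "value"] = merged.reindex(keyed).to_numpy()
    return panel[~panel["indicator"].isin(merge_map.values())].reset_index(drop=True)
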