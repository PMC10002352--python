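"""Synthetic panels, adjacency structures, and LV-consistent series.

Everything the pipeline consumes can be generated here with known ground
truth: per-entity HDI component series (life expectancy observed only at
pseudo-census anchor years, attainment shares, per-capita income), six
industrial and six domestic emission series with log-normal cross-entity
spread plus vehicle-emission series, and a planar lattice adjacency graph
with contiguous region labels.

The coupled-series generator advances the *implicit midpoint* recurrence

    X(t+1) - X(t) = a m + b m^2 + c m n,   m, n the consecutive midpoints,

i.e. exactly the model the estimator fits, so that a noiseless simulate ->
fit round trip recovers the generating coefficients to numerical precision.

The module also packages the published 31-province sign-quadrant fixture
(industrial and domestic, two five-year windows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationDivergenceError
from .indices import (
    DOMESTIC_INDICATORS,
    HDI_EDU_LEVELS,
    HDI_HEALTH,
    HDI_INCOME,
    INDUSTRIAL_INDICATORS,
    VEHICLE_MERGE,
)
from .lv_model import CoupledSeries, build_lv_design

Truth = tuple[float, float, float]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults mirror the real design at desk scale: 16 entities on a 4x4
    lattice, the 2011-2020 decade split into two five-year windows, four
    contiguous regions.
    """

    n_entities: int = 16
    years: tuple[int, ...] = tuple(range(2011, 2021))
    seed: int = 0
    noise_sd: float = 0.0
    indicator_spread: float = 1.0
    graph_scheme: str = "grid"
    n_regions: int = 4

    def __post_init__(self) -> None:
        if self.n_entities < 4:
            raise ConfigurationError("need at least 4 entities")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if len(self.years) < 4:
            raise ConfigurationError("years must span at least one window")
        if not (1 <= self.n_regions <= self.n_entities):
            raise ConfigurationError("n_regions out of range")

    def entity_labels(self) -> list[str]:
        return [f"E{i + 1:02d}" for i in range(self.n_entities)]


# ---------------------------------------------------------------------------
# Implicit-midpoint LV simulation
# ---------------------------------------------------------------------------

def _midpoint_step(current: float, partner_mid: float, truth: Truth) -> float:
    """Advance one series by one implicit-midpoint step.

    With n (the partner midpoint) known, the midpoint m of the stepped
    series solves  b m^2 + (a + c n - 2) m + 2 X(t) = 0; the root nearest
    the current value is taken and the next value is 2m - X(t).
    """
    a, b, c = truth
    p = a + c * partner_mid - 2.0
    if abs(b) < 1e-15:  # linear in m
        if abs(p) < 1e-15:
            raise SimulationDivergenceError("degenerate midpoint relation")
        m = -2.0 * current / p
    else:
        disc = p * p - 8.0 * b * current
        if disc < 0:
            raise SimulationDivergenceError(
                f"no real midpoint root (disc={disc:.3g}): dynamics escaped"
            )
        sq = math.sqrt(disc)
        roots = ((-p + sq) / (2 * b), (-p - sq) / (2 * b))
        m = min(roots, key=lambda r: abs(r - current))
    return 2.0 * m - current


def simulate_lv_pair(truth_i: Truth, truth_h: Truth,
                     initial: tuple[float, float], n_steps: int,
                     noise_sd: float = 0.0,
                     seed: int | np.random.Generator = 0,
                     entity: str = "synthetic",
                     window: tuple[int, int] | None = None) -> CoupledSeries:
    """Simulate a coupled pair from known general-form coefficients.

    Each step solves the two implicit-midpoint relations jointly by
    alternating the per-equation quadratic solves to a fixed point, then
    (optionally) perturbs both increments with independent Gaussian noise.
    """
    if n_steps < 4:
        raise ConfigurationError("n_steps must be >= 4")
    if initial[0] <= 0 or initial[1] <= 0:
        raise ConfigurationError("initial values must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    xs = [float(initial[0])]
    ys = [float(initial[1])]
    for _ in range(n_steps - 1):
        x, y = xs[-1], ys[-1]
        x_next, y_next = x, y
        for _ in range(200):
            x_new = _midpoint_step(x, (y + y_next) / 2.0, truth_i)
            y_new = _midpoint_step(y, (x + x_new) / 2.0, truth_h)
            if abs(x_new - x_next) < 1e-15 and abs(y_new - y_next) < 1e-15:
                x_next, y_next = x_new, y_new
                break
            x_next, y_next = x_new, y_new
        else:
            raise SimulationDivergenceError("midpoint fixed point did not converge")
        if noise_sd > 0:
            x_next += rng.normal(0.0, noise_sd)
            y_next += rng.normal(0.0, noise_sd)
        if x_next <= 0 or y_next <= 0:
            raise SimulationDivergenceError("series left the positive orthant")
        xs.append(x_next)
        ys.append(y_next)
    window = window or (0, n_steps - 1)
    return CoupledSeries(entity=entity, window=window,
                         pollution=tuple(xs), hdi_share=tuple(ys))


def draw_lv_truth(rng: np.random.Generator, n_steps: int = 5,
                  max_condition: float = 1e8, max_tries: int = 200
                  ) -> tuple[Truth, Truth, tuple[float, float]]:
    """Draw random identifiable LV coefficients and initial values.

    Coefficients are sampled in logistic form (growth rate r, carrying
    capacity K, cross-coefficient) and re-expanded to (a, b, c).  Draws
    whose simulated design matrix is ill-conditioned (nearly collinear
    midpoint predictors) or whose dynamics escape the positive orthant are
    rejected — these are exactly the systems the estimator itself refuses.
    """
    for _ in range(max_tries):
        r = rng.uniform(0.2, 0.6, size=2)
        k = rng.uniform(1.5, 3.0, size=2)
        cross = rng.uniform(-0.5, 0.5, size=2)
        truths = []
        for j in range(2):
            b = -r[j] / k[j]
            truths.append((float(r[j]), float(b), float(-cross[j] * b)))
        initial = (float(rng.uniform(0.4, 0.8)), float(rng.uniform(0.4, 0.8)))
        try:
            s = simulate_lv_pair(truths[0], truths[1], initial, n_steps)
        except SimulationDivergenceError:
            continue
        d_i = build_lv_design(s.pollution, s.hdi_share)
        d_h = build_lv_design(s.hdi_share, s.pollution)
        if (np.linalg.cond(d_i.predictors) <= max_condition
                and np.linalg.cond(d_h.predictors) <= max_condition):
            return truths[0], truths[1], initial
    raise ConfigurationError("could not draw an identifiable system")


# ---------------------------------------------------------------------------
# Indicator panel
# ---------------------------------------------------------------------------

def generate_province_panel(spec: SyntheticSpec) -> pd.DataFrame:
    """Long-format indicator panel (entity, year, indicator, value).

    Life expectancy appears only at pseudo-census anchor years (first year,
    mid-decade, last year) so downstream interpolation is exercised.
    Pollution indicators are log-normal with a per-entity level effect and
    a mild declining trend; vehicle NOx and soot series accompany the
    domestic basket for the merge step.
    """
    rng = np.random.default_rng(spec.seed)
    years = list(spec.years)
    anchors = sorted({years[0], years[len(years) // 2], years[-1]})
    rows: list[tuple[str, int, str, float]] = []
    for e in spec.entity_labels():
        # health: rising life expectancy, observed at anchors only
        base_le = rng.uniform(72.0, 80.0)
        slope = rng.uniform(0.05, 0.25)
        for y in anchors:
            rows.append((e, y, HDI_HEALTH,
                         base_le + slope * (y - years[0]) + rng.normal(0, 0.1)))
        # education: attainment shares drifting toward higher levels
        shares = rng.dirichlet([4.0, 5.0, 3.0, 2.0]) * rng.uniform(0.85, 0.95)
        drift = rng.uniform(0.001, 0.006)
        for t, y in enumerate(years):
            shifted = shares + drift * t * np.array([-1.5, -0.5, 0.8, 1.2])
            shifted = np.clip(shifted, 1e-4, None)
            shifted *= min(1.0, 0.97 / shifted.sum())
            for lvl, v in zip(HDI_EDU_LEVELS, shifted):
                rows.append((e, y, lvl, float(v)))
        # income: log-normal level, mild compounding growth
        income0 = float(np.exp(rng.normal(np.log(60_000), 0.35)))
        growth = rng.uniform(1.04, 1.08)
        for t, y in enumerate(years):
            rows.append((e, y, HDI_INCOME,
                         income0 * growth**t * float(np.exp(rng.normal(0, 0.02)))))
        # pollution: entity-level log-normal effect, declining trend
        effect = float(np.exp(rng.normal(0.0, spec.indicator_spread)))
        for ind in INDUSTRIAL_INDICATORS + DOMESTIC_INDICATORS + tuple(
                VEHICLE_MERGE.values()):
            base = float(np.exp(rng.normal(np.log(50.0), 0.3)))
            trend = rng.uniform(0.94, 0.99)
            for t, y in enumerate(years):
                val = (base * effect * trend**t
                       * float(np.exp(rng.normal(0, 0.08))))
                rows.append((e, y, ind, val))
    panel = pd.DataFrame(rows, columns=["entity", "year", "indicator", "value"])
    return panel.sort_values(["entity", "year", "indicator"]).reset_index(drop=True)


def generate_adjacency(spec: SyntheticSpec
                       ) -> tuple[set[tuple[str, str]], dict[str, str]]:
    """Queen lattice edges plus contiguous region labels.

    The entities are laid out on a k x m grid (k the largest factor of
    n_entities not exceeding sqrt(n)); queen edges connect all 8-neighbour
    cells.  Regions are contiguous vertical bands of columns.
    """
    n = spec.n_entities
    k = next((d for d in range(int(math.isqrt(n)), 0, -1) if n % d == 0), 1)
    m = n // k
    if k == 1 and n > 3:
        raise ConfigurationError(
            f"{n} entities do not factor into a 2-d grid"
        )
    labels = spec.entity_labels()

    def lab(r: int, c: int) -> str:
        return labels[r * m + c]

    edges: set[tuple[str, str]] = set()
    for r in range(k):
        for c in range(m):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (dr, dc) == (0, 0) or not (0 <= rr < k and 0 <= cc < m):
                        continue
                    a, b = lab(r, c), lab(rr, cc)
                    if a < b:
                        edges.add((a, b))
    # contiguous vertical bands of columns -> regions
    bounds = np.array_split(np.arange(m), spec.n_regions)
    col_region = {}
    for ridx, cols in enumerate(bounds):
        for c in cols:
            col_region[int(c)] = f"R{ridx + 1}"
    region_of = {lab(r, c): col_region[c] for r in range(k) for c in range(m)}
    return edges, region_of


# ---------------------------------------------------------------------------
# Published sign-quadrant fixture
# ---------------------------------------------------------------------------

def published_fixture() -> pd.DataFrame:
    """The published 31-province force-sign classification.

    Columns: province, window ("2011-2015" / "2016-2020"), pollution_type
    ("industrial" / "domestic"), quadrant (both_positive / pos_neg /
    neg_pos / both_negative).  Each province appears exactly once per
    (window, pollution_type).
    """
    ref = resources.files("lvcoupling").joinpath("data/coupling_quadrants.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


#: Representative force-on pairs for each sign quadrant, used to turn the
#: sign-only fixture into concrete rank assignments where the quadrant
#: fully determines the rank (S and E).
QUADRANT_REPRESENTATIVE = {
    "both_positive": (1.0, 1.0),
    "pos_neg": (1.0, -0.5),
    "neg_pos": (-0.5, 1.0),
    "both_negative": (-1.0, -1.0),
}
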