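# Methods

## Scope and data model

The pipeline consumes a long-format annual indicator panel (entity, year,
indicator, value), an adjacency structure (polygon geometries or an edge
list), and a region-membership table.  It produces, per entity, five-year
window, and pollution type: composite indices, Lotka–Volterra fits,
force-on/mutualism assessments with a six-level rank, and global/local
Moran statistics of the numerically coded ranks under two weight matrices.

## Composite indices

**HDI.** Geometric mean of health, education, and income dimension
indices.  Health rescales life expectancy linearly between goalposts 20
and 85 years; income divides per-capita income by a PPP factor (default
4.184 local currency units per international dollar, the 2017 round) and
rescales the logarithm between 100 and 75,000 international dollars;
education converts attainment shares (primary, junior, senior, tertiary)
to mean schooling years with coefficients (6, 9, 12, 16) and divides by a
16-year maximum.  All goalposts and coefficients are configurable; each
dimension is clamped to [0, 1].  Published analyses of this kind rely on a
national attainment-to-years conversion that is not reprinted anywhere
accessible, so the (6, 9, 12, 16) coefficients are this package's own
default, chosen to match the nominal length of each schooling stage.

Life-expectancy series are typically observed only at census years;
interior gaps are filled by linear interpolation between the nearest
anchors.  Exterior years take the nearest anchor's value (constant
extension): linear extrapolation from two census points can produce
implausible tail values on short panels, and a flat extension is the more
conservative imputation.  The choice is logged whenever it fires.

**HDI share.** Each entity's HDI divided by the national sum, per year.
Shares sum to one by construction; the share series (not the HDI level) is
the development input of the coupling model, so the model tracks the
*relative pace* of development.

**Pollution-control effectiveness.** Each of six emission indicators per
basket (industrial: COD, ammonia nitrogen, SO₂, NOx, smoke/dust, solid
waste; domestic: COD, ammonia nitrogen, SO₂, NOx, smoke/dust, garbage
collection) is a negative indicator standardized by

    x' = 0.6 + 0.4 · (ln x_max − ln x) / (ln x_max − ln x_min),

with extrema pooled over all entities and all years of the analysis
window.  The log tames the order-of-magnitude spread across entities; the
map sends the pooled maximum to exactly 0.6 and the minimum to exactly 1.0
and is strictly decreasing between.  Motor-vehicle NOx and soot emissions
are added onto the domestic NOx and smoke/dust series before
standardization, since household statistics omit the vehicle fleet.

Numerical edge cases: non-positive emissions (a near-zero SO₂ series, say)
are floored at the smallest positive observed value of that indicator with
a warning; a constant indicator (x_max = x_min) returns 1.0 by convention
and is flagged as degenerate.

The six indicator weights default to equal 1/6 — no published weighting
exists for these baskets — and are configurable.  Pooling defaults to
per-window (windows are analyzed as independent studies); a full-period
option exists for sensitivity analysis.  Whether extrema should pool over
years, entities, or both is genuinely open; pooling over both is the
default because the effectiveness index is meant to be comparable across
entities within a window.

## Lotka–Volterra estimation

Each equation of the coupled system is brought to general form
dX/dt = aX + bX² + cXY and discretized with the implicit midpoint scheme
X(t+1) − X(t) = a·m + b·m² + c·m·n, where m and n are consecutive-point
midpoints of the target and partner series.  A window of five annual
observations gives four increments for three coefficients — one degree of
freedom; no regularization is applied, since none is part of the method
being implemented.  The two equations are estimated separately by ordinary
least squares (an SVD solve, verified in tests against the closed-form
normal equations to 1e-8 relative).

Identifiability matters at this sample size: the predictors (m, m², m·n)
are nearly collinear whenever the series barely move or track each other.
A design condition number above 1e10 raises a singular-fit error naming
the entity, window, and equation rather than returning silent garbage; in
lenient pipeline mode such units are excluded from downstream stages and
logged, with n reduced accordingly.

**Coefficient back-map.** Expanding the logistic form gives a = R,
b = −R/K, c = R·(cross)/K for *both* equations, hence K = −a/b and
cross-coefficient = −c/b.  This "consistent" convention is the default.  A
"published-literal" variant (K_H = −a_H/c_H, β = −b_H/c_H for the H equation)
reproduces a published variant of the back-map that does not invert the
expansion; it is retained behind a flag for comparison and the convention
used is recorded in every output row.

## Force-on indices, mutualism degree, rank

The canonical force-on indices are the composite expressions
S_I = K_I/K_H + α and S_H = K_H/K_I + β.  Published closed forms in the
raw (a, b, c) coefficients exist but are not algebraically equal to these
composites under either back-map convention; because the composites carry
the stated interpretation (capacity ratio plus competition coefficient),
they are canonical here, with the closed forms available via
`use_printed_forms=True` for comparison only.

The mutualism degree S₁ = (S_I + S_H)/√(S_I² + S_H²) is the cosine-like
resultant of the force pair: bounded in [−√2, √2], equal to ±√2 iff the
forces are equal, above 1 iff both are positive, below −1 iff both are
negative, and strictly inside (−1, 1) for mixed signs.  The rank is
assigned from the signs and magnitudes directly (S: both positive; A/C:
development promotes pollution control but not conversely, split by which
magnitude dominates; B/D: the reverse; E: both negative); the S₁
thresholds are implied and used as a cross-check.  Values within 1e-12 of
zero count as non-positive and exact magnitude ties resolve to the lower
rank (C/D) — conservative and deterministic.

## Spatial statistics

**Weights.** Queen contiguity links polygons sharing at least one boundary
point (computed with shapely predicates, or supplied as an edge list).
Entities with no neighbour — an island province — are attached through
explicit `extra_links` (a symmetric weight of 1), which also exempts them
from the isolate check; remaining isolates warn, or abort in strict mode.
Region-block weights set w_ij = 1 for distinct entities of the same
economic region.  Whether regional adjacency should replace or union with
physical contiguity is ambiguous in the source description; pure block
membership is the default and a union option exists.  Rows are
standardized to sum to one by default (the convention of the desktop tool
this analysis is usually run in), with binary weights available; the
scheme is recorded alongside every result.

**Rank coding.** S=6 … E=1 by default.  Global Moran's I is invariant
under affine transformations of the attribute, so any equispaced monotone
coding gives the identical statistic; this is tested.

**Global Moran's I.**  I = (n/S₀)·(Σᵢⱼ wᵢⱼ zᵢ zⱼ)/(Σᵢ zᵢ²) with z the
mean deviations; null expectation −1/(n−1).  Inference is Monte-Carlo:
full random relabelings, pseudo-p = (1 + #{permuted I at least as extreme
as observed, in the observed direction relative to E[I]})/(1 + n_perm),
ties counting as extreme, 999 permutations by default, seed-reproducible.

The directional pseudo-p is the field's reporting convention, but
thresholding it at α rejects a true exchangeable null at rate ≈ 2α
(each tail contributes ≈ α).  Results therefore also carry
`p_two_sided = min(1, 2·pseudo_p)`, and the `significant(alpha)` decision
uses it; this is the size-calibrated test, verified empirically in the
suite (rejection rate 10% ± 3% at α = 0.1 over 500 replicates of
exchangeable data on a 4×4 lattice, 199 permutations each).  LISA cluster
*classification* keeps the conventional direct pseudo_p < α rule (α = 0.1
by default) so that cluster tables remain comparable with published
practice.

**Local Moran's I.**  Iᵢ = (zᵢ/m₂)·Σⱼ wᵢⱼ zⱼ with m₂ = Σz²/n, which
aggregates to n·I under row standardization (tested).  Inference is
conditional permutation: the focal value stays fixed and the remaining
n−1 values are drawn without replacement onto the neighbour positions.
Isolates get Iᵢ = 0 and p = 1.  Significant sites are labeled by the sign
pair (own deviation, spatial lag): high–high, low–low, low–high, high–low.

## Synthetic data

The generator emulates the statistical shape of provincial yearbook
panels: life expectancy observed only at pseudo-census anchors (first,
middle, and last year) with a rising trend; attainment shares on a
sub-simplex drifting toward higher education; log-normal per-capita income
with 4–8% annual growth; twelve emission indicators with a log-normal
entity-level spread (σ = 1 by default, matching the order-of-magnitude
cross-entity gaps that motivate the log standardization), mild declining
trends, and multiplicative noise; and vehicle NOx/soot series for the
merge step.  The default scale is 16 entities on a 4×4 queen lattice over
2011–2020 with four contiguous regions — the real design at desk scale,
small enough that the full test suite and the analytic acceptance checks
run in seconds on one CPU.

Coupled series are generated by the *implicit midpoint* recurrence — at
each step the two midpoint relations are solved jointly (per-equation
quadratic in the unknown midpoint, root nearest the current value,
alternated to a fixed point) — so the generator's model is exactly the
estimator's model and a noiseless simulate → fit round trip recovers the
coefficients to numerical precision (~1e-10 observed; 1e-6 asserted).
Optional Gaussian noise perturbs both increments.  Random truth draws are
sampled in logistic form (growth rate 0.2–0.6, carrying capacity 1.5–3,
cross-coefficient ±0.5, initial values 0.4–0.8) and rejection-sampled to
identifiable systems: draws whose simulated design is ill-conditioned
(condition number > 1e8) or whose dynamics leave the positive orthant are
redrawn, mirroring the estimator's own refusal to fit such systems.

What the synthetic study does *not* emulate: real provincial magnitudes,
cross-indicator correlation structure, policy-driven regime changes, or
measurement revisions across statistical calibrations.  Passing tests
demonstrate correctness of the estimator, the classifiers, and the spatial
inference under the model's own assumptions — not that the model is a good
description of any particular real panel.

A packaged fixture carries the published 31-province force-sign
classification (industrial and domestic, 2011–2015 and 2016–2020) as a
quadrant table; sign patterns determine the S and E ranks exactly, and the
suite checks the implied counts.  The published prose reports one count
(10 domestic E-level provinces in 2016–2020) that disagrees with the
corresponding table row (8 provinces); the fixture follows the table and
this note documents the discrepancy rather than resolving it.  The A/C
and B/D splits require unpublished magnitudes and are not reconstructable.

## Known limitations

- Three coefficients fit to four increments leave one degree of freedom;
  estimates are fragile by design and the condition-number guard is the
  only defense.  The method is an index-construction device, not a
  forecasting model; no ODE integration or stability analysis is offered.
- Moran's I on a 6-level ordinal coding treats rank gaps as equal
  intervals; only affine-equivalent codings are guaranteed to agree.
- The permutation calibration statement applies to the two-sided decision;
  the directional pseudo-p alone is anticonservative by a factor of ~2
  under the null, as documented above.
- Headline published values that depend on unpublished province-level
  inputs (global/local Moran magnitudes of the real panel) are out of
  scope; the spatial machinery is validated against analytic identities
  and brute-force oracles instead.
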