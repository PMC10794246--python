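# Methods

## Model and assumptions

The package computes steady-state excess mortality attributable to
long-term ambient PM2.5 exposure on a regular planar grid. Per cell, cause
and adult age class, excess deaths are the product of the baseline
mortality rate, the resident population, and the attributable fraction
AF = (RR − 1)/RR evaluated at the cell's annual-mean concentration. The
central assumptions are:

- **Steady state.** Annual-mean concentration determines annual deaths; no
  lags, cessation dynamics or demographic feedback.
- **TMREL anchoring.** No excess risk at or below the theoretical minimum
  risk exposure level (default 4.15 μg/m³); every risk curve is rescaled so
  each branch equals 1 there. The TMREL is fixed, not sampled from its
  uncertainty range.
- **Country-level baseline rates.** Rates vary by country, cause and age
  class only; they are broadcast to cells through the country mask. Cells
  outside the mask (sea, out of domain) contribute zero deaths regardless of
  concentration.
- **Adult mortality only.** The twelve 5-year age classes from 25–29 to
  80+. Childhood respiratory mortality is out of scope.
- **Uncertainty by bound propagation.** The low/high branches of each curve
  (95 % interval) are propagated as whole curves through every downstream
  sum and difference. This brackets risk-curve uncertainty only — baseline
  rates, population and the TMREL are treated as exact — and the resulting
  intervals are not generally comparable to intervals obtained by sampling.
- **Attribution by mass fraction.** Carbonaceous mortality is total-PM2.5
  mortality times the cell-wise aCA/PM2.5 mass fraction. The two-fold
  toxicity assumption doubles that fraction (capped at 1) while holding
  total PM2.5 mortality constant; risk curves are never re-evaluated at
  inflated concentrations. In the uncapped regime (fraction ≤ 1/factor
  everywhere) the attributed total scales exactly with the factor.
- **Zero-out differencing.** A sector's contribution is BASE minus the
  scenario with the sector's emissions removed. Negative cell differences
  (possible with nonlinear chemistry) are retained and counted, not
  clipped.

## Risk models

Tabulated curves carry knots (μg/m³) with central/low/high RR; evaluation
is piecewise-linear between knots and constant beyond the last knot —
linear interpolation preserves monotonicity and the knot grid can be made
arbitrarily dense. The parametric GEMM-style family
RR(z) = exp(θ·log(1 + z/α)·ω(z)), ω(z) = 1/(1 + exp(−(z − μ)/ν)),
z = max(0, C − counterfactual), is tabulated onto a 0.25 μg/m³ knot grid
for the engine, far below risk-model uncertainty; its low/high branches use
θ ∓ 1.96·θse. The counterfactual defaults to the same 4.15 μg/m³ as the
TMREL (the published 2.4 is available by argument).

## Grids and exposure

Grids are cell-center registered, row-major, origin at the lower-left cell
center, axis-aligned in one planar projection. Concentrations move from
the coarse model grid (e.g. 20 km) to the fine health grid (5 km) by
bilinear interpolation — appropriate for intensive quantities; conservative
remapping is deliberately out of scope. Within the half-cell fringe between
the outer cell centers and the grid boundary, values extend constantly, so
regridded output never leaves the source's [min, max]. The country mask is
never interpolated (each fine cell belongs wholly to one country).
Population weighting uses total adult population by default; a subset of
age classes can be passed as weights. A country with zero population has
no defined weighted mean and raises an error rather than returning 0.

## Key parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| TMREL | 4.15 | μg/m³ | zero-excess-risk anchor for all curves |
| Toxicity factors | 1, 2 | – | aCA mass-fraction multipliers evaluated per run |
| Linearity ε | 0.01 | μg/m³ | cells with a smaller 100 %-removal response are excluded (and counted) from the linearity ratio |
| Regrid method | bilinear | – | concentrations (nearest available; mask never regridded) |
| Health-grid cell | 5 | km | calculation resolution |

Rounding is a reporting-layer concern only: domain totals to the nearest
thousand deaths, country rows to whole deaths, percentages rounded
half-away-from-zero at the caller's number of decimals. All stored
intermediates are double precision and unrounded; report cells render as
"mean (low–high)".

## Synthetic data

The generator emulates the statistical structure of the real inputs — not
their values:

- **Concentration fields.** Per-sector (residential, transport, other,
  background) Gaussian kernel mixtures around one shared set of city
  locations, with a per-sector correlation length and amplitude; the
  sector's carbonaceous mass is a fixed share of its PM2.5 (defaults 0.45 /
  0.25 / 0.10 / 0.02). Defaults put country population-weighted PM2.5 in
  roughly 3–21 μg/m³ and carbonaceous fractions in the few-percent-to-20 %
  range, the magnitudes typical of the European domain, and keep every
  cell's fraction below 0.5 so the two-fold rule operates uncapped.
- **Scenario composition.** PM2.5 = background + Σ emission-scaled sectors
  + γ × a normalized symmetric quadratic term in the scaled sector fields.
  The quadratic term includes self-pairs: pure cross products are linear in
  any single sector's emission scaling, so only the self-interaction makes
  a one-sector scenario response genuinely nonlinear — the behaviour the
  linearity diagnostic exists to detect. γ = 0 gives exact additivity, so
  BASE − RES100 equals the residential field identically and the linearity
  ratio is 1 in every valid cell. The quadratic term carries no
  carbonaceous mass (it stands for secondary inorganic formation).
- **Population.** A city-kernel surface raised to a clustering exponent
  (default 1.5) times log-normal noise, plus an additive rural floor so no
  country block is empty; normalized to the spec total (default 40 million
  adults over a 60×60 grid) and rounded to whole persons. Age split is a
  fixed old-skewed distribution over the twelve classes.
- **Countries.** Voronoi cells of random seed points (hence contiguous),
  with a two-cell sea rim exercising the out-of-mask path.
- **Baseline rates.** Per country and cause, an all-age mean drawn within a
  plausible per-cause range, with rates doubling per decade of age.
- **Risk curves.** Saturating exponentials in the excess over the TMREL —
  monotone, concave (supralinear at low concentrations), steepest near the
  TMREL — with low/high branches scaling the excess risk by 0.75/1.30 and
  per-age attenuation for the cardiovascular causes.

All randomness derives from one integer seed via per-artifact CRC-keyed
streams, so every generated object is identical across runs and the
generation order of artifacts does not matter.

What the generator does **not** emulate: meteorology and seasonality,
chemical speciation beyond the PM2.5/aCA pair, coastline geometry and
fractional border cells, sub-national rate variation, migration or age
structure varying in space. Passing tests therefore demonstrate the
correctness of the assessment arithmetic and its invariances — not that
real chemistry-transport output composes additively, nor the realism of
any absolute death toll computed from synthetic inputs.

## Numerical choices

- Knot interpolation is linear in (concentration, RR); extrapolation
  beyond the last knot is constant.
- aCA/PM2.5 division returns 0 where PM2.5 = 0 and clamps to [0, 1] with a
  logged warning — empty cells carry no attributable mass.
- Accumulation is double precision, stratum-major; sums over country
  partitions match the domain total to ~1e-9 relative.
- The mortality engine is vectorized per (cause, age, branch) stratum; its
  agreement with a literal per-cell scalar loop is enforced at 1e-9
  relative in the test suite.
- Degenerate 1-row/1-column source grids fall back to per-axis
  interpolation.

## Design choices made where the design was open

- Population weighting uses adult totals (the population the mortality sum
  operates on); a per-age-class switch is exposed since published exposure
  tables rarely state which population the weighting used.
- CI propagation by whole-curve bounds (above) rather than Monte Carlo:
  simple, deterministic, and honest about covering risk-curve uncertainty
  only.
- Age-invariant causes (COPD, lung cancer, respiratory infection, diabetes)
  apply one curve to each age class with age-specific rates and population,
  because the mortality sum requires per-age terms even when RR is
  age-invariant.
- The two-fold toxicity rule reweights the mass fraction rather than
  re-running risk curves at inflated concentrations; the cap at 1 keeps
  attribution within the total for any factor.
- Raster I/O is classic NetCDF through xarray's scipy backend; tabular
  interchange is CSV written with round-trip float precision. Rounding
  exists only in rendered reports.

## Problem sizes

The unit suite cross-checks on 10×10 grids; pipeline and acceptance
properties run the default 60×60, 4-country study (3 600 cells, 216
strata), sized so the full suite completes in well under a minute on one
core. The brute-force oracle comparisons use 8×8–10×10 grids where the
scalar loop is cheap.

## Known limitations

- Bound-propagated intervals understate total uncertainty (no baseline-rate,
  population or TMREL components) and need not match intervals produced by
  other propagation schemes.
- Attribution by mass fraction assumes cause- and age-invariant toxicity
  weighting; it cannot express component-specific risk curves.
- The linearity diagnostic is a domain mean over valid cells; strong
  spatially-compensating nonlinearities could still average near 1.
- No map projections: all grids must already share one planar coordinate
  system.
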