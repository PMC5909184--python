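# Methods

This note documents the models inside `eonrcast`: what they compute, the
assumptions they make, the parameters that matter, and what the synthetic
test bed does and does not demonstrate about real fields.

## 1. The forecasting protocol

A forecast is made for one *study year* at one *forecast time* — planting,
6th leaf (V6), 12th leaf (V12), silking (R1) or physiological maturity (R6).
The weather driver for each ensemble member is a spliced series: the study
year's observed daily weather through the forecast day, one historical donor
year's weather after it. Stage dates anchoring the splice are computed from
the study year's observed weather — exactly what a forecaster standing in
the field at that stage would know. The planting-time forecast uses observed
weather only up to the planting day; the maturity forecast uses the complete
observed year, so its ensemble is degenerate by construction (all members
identical, SD exactly 0 — enforced in code by returning an exact zero when
all member values are bit-identical, since a naive `mean`/`std` of n equal
floats can be off by one ulp).

Donor years come from one of six selection rules: the full library
(`full35`, the standard approach), the 5/10/20 calendar years immediately
preceding the study year (`III`/`IV`/`V`), or analog years whose annual
(`I`) or summer, June–August (`II`) temperature/precipitation anomaly
quadrant matches the study year's. "Same quadrant" operationalizes "similar
weather pattern" as agreeing in the *sign* of both anomalies versus the
library long-term mean; exact ties resolve to warm/wet so the four quadrants
partition any library. This is a documented design choice — pattern
similarity could also be defined on within-season distributions — and it is
the weakest link of scenarios I/II, since two years with equal totals can
have very different rainfall timing.

Per member, the simulator runs at every rate of the trial design
(0/67/134/201/268 kg N/ha by default) from the *same* starting soil state; a
response curve is fitted per member and the EONR distribution summarized by
its mean and sample SD. Across study years the soil state advances
*sequentially* on the realized (fully observed) season at a fixed reference
rate of 134 kg N/ha — the middle of the design — so that every forecast cell
of a year starts from an identical carried-over state regardless of forecast
time, and forecasts never contaminate the carryover trajectory. An optional
reset flag restores the initial state each year instead.

Members whose season fails (maturity not reached by day 365) are flagged and
excluded from the aggregates, with counts reported; if *every* member fails
(an extreme cold year), the cell aggregates the flagged zero-yield responses
rather than aborting, so a factorial design always completes.

## 2. The crop–soil simulator

The simulator is a minimal daily-timestep process model, not a calibrated
cropping-systems platform. It exists to give the forecasting machinery a
deterministic, mass-conserving crop response with a genuine weather × N
interaction. State: plant-available water (single bucket, capacity 250 mm),
inorganic N, a mineralizable organic-N pool, and surface residue.

Daily order of operations: mineralization → fertilizer (on its application
day) → infiltration/runoff/drainage → transpiration and evaporation →
leaching → crop N uptake.

* **Phenology.** Thermal time `max(0, (tmax+tmin)/2 − 10 °C)` accrues from
  the day after sowing; stages fire at cumulative targets V6 = 280,
  V12 = 560, R1 = 760, R6 = 1250 °C·d. These place V6 in mid-June, silking
  in mid-July and maturity in early September for a planting day of 120 in a
  9 °C-mean climate, and make maturity failure the rare cold-summer event it
  is in reality. (The GDD accumulator itself, `accumulate_gdd`, includes its
  start day; `stage_date` starts the clock the day after sowing.)
* **Water.** Rain below 20 mm/d infiltrates fully; half of the excess above
  runs off. The bucket spills to drainage above capacity. Transpiration
  demand is `0.17 mm per MJ m⁻²` at full canopy (canopy fraction = thermal
  time / R1 target, capped at 1), supply is 5 %/d of stored water; bare-soil
  evaporation uses the canopy complement at `0.05 mm/MJ`. The water-stress
  index is seasonal transpiration / demand, clipped to [0.05, 1].
* **Nitrogen.** First-order mineralization of the organic pool
  (0.8 × 10⁻⁴ d⁻¹ at optimum) and of residue (3 × 10⁻³ d⁻¹, 0.8 % N),
  both scaled by a linear temperature factor (0 at 0 °C, 1 at 25 °C) and by
  relative soil water. Leaching removes the fraction
  `min(1, 0.3 · drainage/capacity)` of inorganic N on drainage days — the
  mechanism that makes wet springs demand more fertilizer. Crop demand
  (230 kg N/ha season total at potential yield) accrues with thermal time;
  daily uptake is the smaller of the outstanding demand and 12 %/d of
  inorganic N, so early-season shortfalls can be caught up later. The
  N-stress index is seasonal uptake / demand.
* **Yield.** `potential_yield × min(water stress, N stress)` with
  potential 13 Mg/ha at 15.5 % moisture (law of the minimum). This produces
  a concave, plateauing N response because low-N uptake is supply-limited
  through the daily-access fraction while losses rise with the size of the
  inorganic pool.
* **Rotation.** Soybean years are not simulated; a corn-after-soybean season
  starts with a 45 kg N/ha credit and 40 % of the carried residue. This is
  the entire representation of the two-year rotation and is the reason
  soybean–corn EONR forecasts sit well below continuous-corn ones.

Per season, the inorganic-N ledger (initial + fertilizer + credit +
mineralized = uptake + leached + final) and the water ledger close to well
below 10⁻⁶; both are asserted in the test suite. Yield is non-decreasing in
N rate by construction (uptake is monotone in the inorganic pool) and is
verified over the design plus a 400 kg N/ha luxury rate.

Known limitations: no radiation-driven biomass accumulation, no water table
(which buffers drought in the real landscape the defaults imitate — dry-year
behavior here is more severe than observed), no denitrification or
volatilization (all non-uptake loss flows through the leaching term), no
tillage, single-layer soil.

## 3. Response fitting and the EONR

Quadratic fits are ordinary least squares; quadratic-plus-plateau fits are
bounded nonlinear least squares (c < 0) restarted from the quadratic
solution and from vertex guesses at each interior design rate, keeping the
best SSE — deterministic given the data. The plateau is parameterized by the
smooth join `N₀ = −b/(2c)` (continuity and zero slope), keeping three free
parameters and nesting comparability with the quadratic. Significance is the
regression F-test against the mean-only model at p < 0.05 — with five design
points that is an F(2, 2) test, deliberately conservative — plus a concavity
requirement (`c ≤ 0`; for the plateau form `c ≤ −10⁻⁶`, so strictly linear
data are flagged rather than fitted with a vanishing curvature). Among
significant fits the smaller SSE wins; an exact tie goes to the plateau
form. Nonsignificant responses map to EONR = 0 with an explicit
`nonsignificant` flag instead of a dropped observation, so ensembles always
aggregate a defined value; the flag propagates to reports, and evaluation
against observed truth excludes years whose *observed* optimum is undefined.

The closed-form optimum `(R − b)/(2c)` is clipped to the tested range
[0, 268] — extrapolating a fitted quadratic beyond the design is not
defensible — with the clipping recorded in a boundary flag. Responses are
fitted in kg grain/ha so the derivative threshold is the price ratio
(5.6 kg grain per kg N) directly, with no unit conversion. An independent
brute-force check (`profit_grid_eonr`, argmax of `y(N) − R·N` on a 0.01
kg N/ha grid) validates the closed form in the tests for a thousand random
concave responses.

## 4. The synthetic test bed

The weather generator targets a humid continental climate: sinusoidal annual
temperature (mean 9 °C, amplitude 15 °C) with AR(1) daily noise (sd 2 °C,
ρ = 0.7) and a year-level shift (sd 0.7 °C); two-state Markov precipitation
(mean wet probability 0.26, +0.15 persistence, seasonal cycle) with
gamma-distributed wet-day amounts normalized against the chain's stationary
wet probability so the long-run mean hits 900 mm/yr, and a mean-one
lognormal year factor (sd 0.22) creating wet and dry years; solar radiation
with a seasonal cycle and wet-day dimming. The interannual spread was chosen
so that season GDD varies about ±10 % — wide enough to produce all four
anomaly quadrants in a 35-year library (regenerated with an incremented
child seed until every quadrant holds ≥ 3 years; attempts logged) and an
occasional maturity-failure year, narrow enough that such failures stay
rare. It has no spell-length calibration, no radiation–temperature coupling
beyond the wet-day dimming, and no trends; it exercises the pipeline rather
than emulating any particular place.

"Observed" truth is the forecasting simulator with perturbed parameters
(defaults: mineralization × 1.2, potential yield × 0.9; bounds ± 20 %) run
over the study years under the same sequential protocol, plus multiplicative
lognormal yield noise with a 5 % CV — typical small-plot trial variability.
Misspecification and noise are how the test bed emulates the model-vs-reality
gap; setting both to zero makes the maturity forecast reproduce the observed
EONR *exactly* in every year, the pipeline's strongest self-test, asserted
bit-for-bit in the acceptance suite.

What passing these tests shows: the machinery (splicing, simulation,
fitting, aggregation, scoring) is internally consistent, conservative, and
deterministic. What it does not show: that the stand-in simulator's skill
numbers transfer to any real site — real weather has spell structure and
extremes the generator lacks, and real model error is not a clean parameter
perturbation.

## 5. Numerical choices and problem sizes

Sample (ddof = 1) standard deviations throughout; an all-equal guard returns
exact zeros for collapsed ensembles. The noisy-recovery Monte Carlo uses 500
replicates; the closed-form-vs-grid check 1,000 random responses at a 0.01
kg N/ha grid step. The test suite's factorial check runs the full
paper-shaped design (22,400 simulator runs) in well under two minutes; the
acceptance script's complete regeneration — library, truth, factorial,
Monte Carlos, scenario comparison — takes a few minutes on one CPU. A note
on the statistics of five-point designs: with 5 % CV yield noise the
sampling SD of a single-year EONR estimate is ~30 kg N/ha (the F(2, 2)
significance test and range clipping add heavy tails), so per-year EONR
recovery errors of 20–30 kg N/ha are the statistical floor of the design
itself, not an estimator defect; the median *estimate* stays within a few
kg N/ha of the truth. This is why observed EONR series are noisy benchmarks
and why directional (above/at/below site mean) scoring is reported alongside
RMSE-based skill.
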