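# eonrcast

In-season ensemble forecasting of corn yield and the **economic optimum
nitrogen rate (EONR)** from spliced observed/historical weather.

## The problem

Corn growers must commit to a nitrogen fertilizer rate early in the season,
long before the weather that actually determines that year's optimum rate has
happened. The EONR — the rate N* at which the marginal yield gain equals the
fertilizer:grain price ratio — varies strongly from year to year with
rainfall-driven N losses and mineralization, so a long-run average
recommendation misses badly in wet or dry years.

`eonrcast` implements a forecasting protocol for this decision: at a
phenological forecast time (planting, V6, V12, silking R1, or maturity R6),
combine the weather *observed so far* with each historical year's weather for
the *remainder* of the season, run a process-based corn–soil N simulator for
every spliced weather realization at every rate of a fertilizer trial design,
fit a yield–N response per ensemble member, and read off a distribution of
EONR forecasts. As the season advances the historical tail shrinks and the
ensemble collapses; at maturity the spread is exactly zero.

## The model

For each ensemble member the five-rate design (0, 67, 134, 201, 268 kg N/ha)
yields five simulated yields, to which the two standard agronomic response
forms are fitted:

- quadratic: `y = a + bN + cN²`
- quadratic-plus-plateau: the same quadratic up to its vertex
  `N₀ = −b/(2c)`, constant beyond it (smooth join, zero slope).

Among fits significant at p < 0.05 (regression F-test, concave curvature)
the smaller-SSE form is selected, and the optimum follows from the
first-order condition `dy/dN = R`:

    N* = (R − b) / (2c),   clipped to [0, 268],

with `R = 5.6` kg grain per kg N the default price ratio. `YEONR` is the
fitted yield at `N*`. Forecast skill is scored with RMSE and relative RMSE
(RRMSE ≤ 15 % good, 15–30 % moderate, ≥ 30 % poor), directional accuracy
against the across-year site-mean EONR (above / at / below, ± 30 kg N/ha
band), categorical N-need bias tables, and analog-scenario ΔRRMSE.

The simulator is a deliberately small daily-timestep stand-in for a full
cropping-systems model — a bucket water balance, two-pool N dynamics
(mineralization, residue, drainage-driven leaching, demand-limited uptake),
GDD phenology and a law-of-the-minimum yield — documented in
[docs/methods.md](docs/methods.md). Seasons chain without annual
re-initialization, so residual soil water, N and residue carry over between
years; a synthetic-data module generates multi-decade weather libraries and
perturbed-truth "observed" experiments so the whole pipeline runs with no
external data.

## Worked example

```bash
python examples/forecast_uncertainty.py
```

```
ensemble EONR forecast for 2004 (donors: all 12 library years)
    stage  splice day  EONR mean  EONR SD
 planting         120      229.0    15.81
       V6         162      230.1     6.41
      V12         181      231.9     3.86
       R1         197      230.1     2.43
       R6         365      227.0     0.00
```

Each row is one forecast cell: observed weather up to the splice day, one
ensemble member per historical donor year after it. At planting the grower
faces ± 16 kg N/ha of weather-driven uncertainty around a ~229 kg N/ha
optimum; by silking most of the season is known and the spread has fallen to
± 2; at maturity the weather is fully observed, every member is identical,
and the SD is exactly zero. The other examples build the weather library and
analog scenarios (`weather_library.py`), fit a single season's response and
cross-check the EONR against a brute-force profit search
(`season_response.py`), and score forecasts against a synthetic observed
truth (`forecast_skill.py`).

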