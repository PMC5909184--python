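"""Score planting-time EONR forecasts against a synthetic observed truth:
RRMSE with agreement category, and directional accuracy versus the site mean.

The "observed" truth comes from a perturbed copy of the simulator (faster
mineralization, lower potential yield) plus 5% plot-level yield noise, so the
forecasting model is deliberately misspecified relative to reality.

Run:  python examples/forecast_skill.py
"""

import numpy as np

from eonrcast import (
    ForecastConfig,
    TruthConfig,
    WeatherGenConfig,
    build_directional_records,
    directional_accuracy,
    generate_observed_truth,
    generate_weather_library,
    run_full_design,
    skill,
)

lib = generate_weather_library(WeatherGenConfig(n_years=12, start_year=1995, seed=3))
study_years = tuple(lib.years[-6:])

truth = generate_observed_truth(lib, study_years, TruthConfig(seed=9))
cfg = ForecastConfig(
    study_years=study_years,
    forecast_times=("planting",),
    scenarios=("full35",),
    rotations=("continuous_corn",),
)
cells, ledger = run_full_design(cfg, lib, initial_soil=truth.initial_soil)
print(f"ran {ledger.forecast_runs} simulator runs "
      f"({len(study_years)} years x {len(lib)} members x 5 N rates)")

valid = [y for y in study_years
         if truth.eonr_results[y].boundary_flag != "nonsignificant"]
obs = np.array([truth.observed_eonr[y] for y in valid])
pred = np.array([next(c.eonr_mean for c in cells if c.year == y) for y in valid])

print(f"\n{'year':>6} {'observed':>9} {'forecast':>9}")
for y, o, p in zip(valid, obs, pred):
    print(f"{y:>6} {o:>9.1f} {p:>9.1f}")

rep = skill(obs, pred)
print(f"\nRMSE  : {rep.rmse:6.1f} kg N/ha")
print(f"RRMSE : {rep.rrmse_percent:6.1f} %  -> '{rep.agreement_category}' agreement "
      "(<=15% good, 15-30% moderate, >=30% poor)")

site_mean_obs = float(obs.mean())
records = build_directional_records(valid, "continuous_corn", obs, pred, site_mean_obs)
acc = directional_accuracy(records)
print(
    f"\ndirection vs site mean ({site_mean_obs:.0f} +/- 30 kg N/ha band): "
    f"{acc['n_correct']}/{acc['n_total']} years called correctly"
)
print(
    "A correct call means the forecast put the year on the same side of the\n"
    "long-run average N need (above / at / below) as the observed optimum."
)
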