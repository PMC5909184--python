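"""Forecast skill scoring against observed truth.

Implements the evaluation conventions of agronomic model testing:

* RMSE and relative RMSE (RRMSE = 100 * RMSE / mean(observed), in percent)
  with agreement categories: RRMSE <= 15% "good", 15–30% "moderate",
  >= 30% "poor" (both boundaries inclusive on their side: exactly 15.0 is
  good, exactly 30.0 is poor);
* directional classification of annual values against the across-year site
  mean: "above" / "at" / "below", where "at" means within a +/-30 kg N/ha
  band of the site mean (the same threshold used for calling an EONR
  prediction accurate);
* N-need categories of years (high need / average / low need, site mean
  +/- 30 kg N/ha on the *observed* EONR) with mean prediction bias per
  category;
* scenario deltas: RRMSE of an analog-weather scenario minus RRMSE of the
  full-record baseline — positive means the full record forecast better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DIRECTION_BAND",
    "SkillReport",
    "DirectionalRecord",
    "ScenarioDelta",
    "skill",
    "agreement_category",
    "classify_direction",
    "build_directional_records",
    "directional_accuracy",
    "n_need_category",
    "n_need_bias",
    "scenario_deltas",
]

#: kg N/ha half-width of the "at site mean" band and the accuracy threshold
DIRECTION_BAND = 30.0

GOOD_BOUND = 15.0
POOR_BOUND = 30.0


@dataclass(frozen=True)
class SkillReport:
    rmse: float
    rrmse_percent: float
    agreement_category: str  # good | moderate | poor
    n_pairs: int


@dataclass(frozen=True)
class DirectionalRecord:
    """One year's direction call of predicted vs observed against a site mean."""

    year: int
    rotation: str
    observed_class: str   # above | at | below
    predicted_class: str
    correct: bool
    abs_error: float      # |predicted - observed| EONR, kg N/ha
    within_threshold: bool  # abs_error < DIRECTION_BAND


@dataclass(frozen=True)
class ScenarioDelta:
    scenario: str
    forecast_time: str
    target: str                 # "yield" | "eonr"
    delta_rrmse_percent: float  # scenario minus baseline; positive = baseline better


def agreement_category(rrmse_percent: float) -> str:
    if rrmse_percent <= GOOD_BOUND:
        return "good"
    if rrmse_percent >= POOR_BOUND:
        return "poor"
    return "moderate"


def skill(observed, predicted) -> SkillReport:
    """RMSE / RRMSE of predictions against observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 pairs")
    mean_obs = obs.mean()
    if mean_obs <= 0:
        raise ValueError("RRMSE undefined: mean of observed is not positive")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    rrmse = 100.0 * rmse / float(mean_obs)
    return SkillReport(
        rmse=rmse,
        rrmse_percent=rrmse,
        agreement_category=agreement_category(rrmse),
        n_pairs=int(obs.size),
    )


def classify_direction(
    value: float, site_mean: float, band: float = DIRECTION_BAND
) -> str:
    """"above" / "at" / "below" the site mean, with an ``at`` half-width band."""
    if band < 0:
        raise ValueError("band must be >= 0")
    if value > site_mean + band:
        return "above"
    if value < site_mean - band:
        return "below"
    return "at"


def build_directional_records(
    years,
    rotation: str,
    observed,
    predicted,
    site_mean_value: float,
    band: float = DIRECTION_BAND,
) -> list[DirectionalRecord]:
    """Directional records for one rotation's annual observed/predicted EONRs.

    Both series are classified against the *observed* site mean, matching the
    benchmarking convention of judging forecasts by the direction they call
    relative to the long-run average.
    """
    recs = []
    for year, obs, pred in zip(years, observed, predicted):
        ocls = classify_direction(obs, site_mean_value, band)
        pcls = classify_direction(pred, site_mean_value, band)
        err = abs(pred - obs)
        recs.append(
            DirectionalRecord(
                year=int(year), rotation=rotation,
                observed_class=ocls, predicted_class=pcls,
                correct=(ocls == pcls), abs_error=float(err),
                within_threshold=bool(err < band),
            )
        )
    return recs


def directional_accuracy(records: list[DirectionalRecord]) -> dict:
    """Counts and error summaries of direction calls.

    ``mean_abs_error_correct`` averages |error| over the correctly-classified
    subset (the headline convention); ``mean_abs_error_all`` is the
    everything-included variant, clearly labeled. An empty correct subset
    reports NaN.
    """
    if not records:
        raise ValueError("no directional records")
    n_total = len(records)
    correct = [r for r in records if r.correct]
    errs_correct = np.array([r.abs_error for r in correct])
    errs_all = np.array([r.abs_error for r in records])
    return {
        "n_correct": len(correct),
        "n_total": n_total,
        "fraction_correct": len(correct) / n_total,
        "mean_abs_error_correct": (
            float(errs_correct.mean()) if len(correct) else float("nan")
        ),
        "mean_abs_error_all": float(errs_all.mean()),
        "n_within_threshold": int(sum(r.within_threshold for r in records)),
    }


def n_need_category(
    observed_eonr: float, site_mean_value: float, band: float = DIRECTION_BAND
) -> str:
    """high_need / average / low_need from observed EONR vs site mean +/- band."""
    if observed_eonr > site_mean_value + band:
        return "high_need"
    if observed_eonr < site_mean_value - band:
        return "low_need"
    return "average"


def n_need_bias(
    records: pd.DataFrame, band: float = DIRECTION_BAND
) -> pd.DataFrame:
    """Mean predicted-minus-observed EONR per N-need category.

    ``records`` needs columns ``year, rotation, forecast_time, observed_eonr,
    predicted_eonr, site_mean``. Returns mean bias per
    (forecast_time x category x rotation); empty cells are absent (NaN after
    pivoting).
    """
    required = {
        "year", "rotation", "forecast_time", "observed_eonr",
        "predicted_eonr", "site_mean",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing column(s) {sorted(missing)}")
    df = records.copy()
    df["category"] = [
        n_need_category(o, s, band)
        for o, s in zip(df["observed_eonr"], df["site_mean"])
    ]
    df["bias"] = df["predicted_eonr"] - df["observed_eonr"]
    table = (
        df.groupby(["forecast_time", "category", "rotation"])["bias"]
        .mean()
        .unstack("rotation")
    )
    return table


def scenario_deltas(
    per_scenario: dict[tuple[str, str, str], SkillReport],
    baseline: dict[tuple[str, str], SkillReport],
) -> list[ScenarioDelta]:
    """RRMSE differences scenario-minus-baseline.

    ``per_scenario`` is keyed by (scenario, forecast_time, target) and
    ``baseline`` by (forecast_time, target). Positive deltas mean the
    full-record baseline forecast better.
    """
    out = []
    for (scenario, ft, target), rep in sorted(per_scenario.items()):
        key = (ft, target)
        if key not in baseline:
            raise KeyError(f"missing baseline skill for {key}")
        out.append(
            ScenarioDelta(
                scenario=scenario,
                forecast_time=ft,
                target=target,
                delta_rrmse_percent=rep.rrmse_percent - baseline[key].rrmse_percent,
            )
        )
    return out
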