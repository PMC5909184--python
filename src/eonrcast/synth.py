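"""Synthetic inputs: a stochastic weather generator and a perturbed-truth
"field experiment".

The weather generator emulates a humid continental Corn Belt climate: a
sinusoidal annual temperature cycle around a ~9 degC mean, a two-state
(wet/dry) Markov precipitation chain with gamma-distributed wet-day amounts
targeting ~900 mm/yr, a solar-radiation annual cycle with wet-day dimming,
and year-level temperature and precipitation anomalies large enough that a
multi-decade library populates all four warm/cold x wet/dry anomaly
quadrants. It is intentionally simple — no spell-length calibration, no
spatial structure — because its job is to exercise the forecasting pipeline,
not to be a climate model.

"Observed" truth is produced by running a *perturbed* copy of the crop
simulator (by default faster mineralization and lower potential yield than
the forecasting configuration, emulating model-vs-reality misspecification)
sequentially over the study years at the five-rate trial design, then adding
multiplicative lognormal observation noise to each plot-year yield and
fitting the observed response. With zero noise and zero misspecification the
truth run is bit-identical to the forecasting simulator's own known-weather
run, which gives the pipeline an exact end-to-end self-test.

All randomness flows from explicit seeds through ``numpy`` Generators;
identical seeds give identical outputs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cropsim import (
    ManagementConfig,
    SimConfig,
    SoilState,
    default_initial_soil,
    run_season,
)
from .response import DEFAULT_N_RATES, DEFAULT_PRICE_RATIO, EonrResult, NResponseData, eonr_from_data
from .weather import DAYS_PER_YEAR, WeatherLibrary, WeatherSeries, classify_year

__all__ = [
    "WeatherGenConfig",
    "TruthConfig",
    "ObservedTruth",
    "generate_weather_library",
    "generate_observed_truth",
]

logger = logging.getLogger(__name__)


@dataclass
class WeatherGenConfig:
    """Climatology targets and variability of the weather generator."""

    n_years: int = 35
    start_year: int = 1980
    seed: int = 0
    mean_annual_temp: float = 9.0      # degC
    temp_amplitude: float = 15.0       # degC, half-range of the annual cycle
    temp_year_sd: float = 0.7          # degC, interannual mean-shift SD
    temp_daily_sd: float = 2.0         # degC, AR(1) daily noise SD
    temp_daily_rho: float = 0.7        # AR(1) autocorrelation
    diurnal_range: float = 10.0        # degC, tmax - tmin
    target_annual_precip: float = 900.0  # mm
    wet_prob: float = 0.26             # mean daily wet probability
    wet_prob_seasonal_amp: float = 0.08
    wet_persistence: float = 0.15      # added P(wet|wet)
    gamma_shape: float = 0.75          # wet-day amount shape
    precip_year_sd: float = 0.22       # lognormal SD of year precip factor
    radiation_mean: float = 17.0       # MJ/m2/d annual mean
    radiation_amplitude: float = 9.0
    radiation_daily_sd: float = 2.0
    wet_day_dimming: float = 0.7       # radiation multiplier on wet days
    min_quadrant_years: int = 3        # required per annual quadrant (n>=30)
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")


def _generate_year(
    cfg: WeatherGenConfig, year: int, rng: np.random.Generator
) -> WeatherSeries:
    doy = np.arange(1, DAYS_PER_YEAR + 1)
    phase = 2.0 * np.pi * (doy - 15) / DAYS_PER_YEAR  # coldest mid-January

    t_clim = cfg.mean_annual_temp - cfg.temp_amplitude * np.cos(phase)
    t_shift = rng.normal(0.0, cfg.temp_year_sd)
    eps = np.empty(DAYS_PER_YEAR)
    innov_sd = cfg.temp_daily_sd * np.sqrt(1.0 - cfg.temp_daily_rho**2)
    eps[0] = rng.normal(0.0, cfg.temp_daily_sd)
    for i in range(1, DAYS_PER_YEAR):
        eps[i] = cfg.temp_daily_rho * eps[i - 1] + rng.normal(0.0, innov_sd)
    tmean = t_clim + t_shift + eps
    tmax = tmean + cfg.diurnal_range / 2.0
    tmin = tmean - cfg.diurnal_range / 2.0

    # precipitation: seasonal wet probability, Markov persistence, gamma amounts
    pwet = np.clip(
        cfg.wet_prob
        + cfg.wet_prob_seasonal_amp * np.sin(2.0 * np.pi * (doy - 105) / DAYS_PER_YEAR),
        0.02, 0.95,
    )
    # mean-one year factor (lognormal), so the long-run mean hits the target
    year_factor = float(
        np.exp(rng.normal(-0.5 * cfg.precip_year_sd**2, cfg.precip_year_sd))
    )
    # normalize wet-day amounts against the Markov chain's stationary wet
    # probability and the seasonal amount profile, so E[annual total] = target
    p_wet_given_dry = np.clip(pwet - 0.05, 0.02, 0.95)
    p_wet_given_wet = np.clip(pwet + cfg.wet_persistence, 0.02, 0.95)
    pi_wet = p_wet_given_dry / (1.0 - p_wet_given_wet + p_wet_given_dry)
    profile = 1.0 + 0.5 * np.sin(2.0 * np.pi * (doy - 135) / DAYS_PER_YEAR)
    base_scale = cfg.target_annual_precip / (
        cfg.gamma_shape * float(np.sum(pi_wet * profile))
    )
    scale_clim = base_scale * profile
    wet = np.zeros(DAYS_PER_YEAR, dtype=bool)
    prev_wet = rng.random() < pwet[0]
    for i in range(DAYS_PER_YEAR):
        p = np.clip(pwet[i] + (cfg.wet_persistence if prev_wet else -0.05), 0.02, 0.95)
        wet[i] = rng.random() < p
        prev_wet = wet[i]
    amounts = rng.gamma(cfg.gamma_shape, scale_clim) * year_factor
    precip = np.where(wet, amounts, 0.0)

    radn = (
        cfg.radiation_mean
        - cfg.radiation_amplitude * np.cos(phase)
        + rng.normal(0.0, cfg.radiation_daily_sd, DAYS_PER_YEAR)
    )
    radn = np.where(wet, radn * cfg.wet_day_dimming, radn)
    radn = np.maximum(radn, 0.5)

    return WeatherSeries(
        year_label=year, tmax=tmax, tmin=tmin, precip=precip,
        radiation=radn, provenance="historical",
    )


def generate_weather_library(cfg: WeatherGenConfig | None = None) -> WeatherLibrary:
    """Generate an ``n_years`` historical weather library.

    Deterministic given the seed. For libraries of 30+ years the generator
    retries with an incremented child seed (attempts logged) until every
    annual anomaly quadrant holds at least ``min_quadrant_years`` years, so
    analog selection always has material to work with.
    """
    cfg = cfg or WeatherGenConfig()
    require_quadrants = cfg.n_years >= 30
    for attempt in range(cfg.max_attempts):
        seed = np.random.SeedSequence([cfg.seed, attempt])
        rng = np.random.default_rng(seed)
        lib = WeatherLibrary()
        for k in range(cfg.n_years):
            lib.add(_generate_year(cfg, cfg.start_year + k, rng))
        if not require_quadrants:
            return lib
        counts: dict[tuple[str, str], int] = {}
        for y in lib.years:
            q = classify_year(lib, y, "annual").quadrant
            counts[q] = counts.get(q, 0) + 1
        if len(counts) == 4 and min(counts.values()) >= cfg.min_quadrant_years:
            if attempt:
                logger.info("quadrant balance reached after %d attempts", attempt + 1)
            return lib
        logger.info("attempt %d: quadrant census %s, regenerating", attempt + 1, counts)
    raise ValueError(
        f"could not populate all four annual quadrants with "
        f">={cfg.min_quadrant_years} years in {cfg.max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# observed truth
# ---------------------------------------------------------------------------


@dataclass
class TruthConfig:
    """How "reality" differs from the forecasting model.

    The truth simulator is the forecasting simulator with perturbed
    parameters (bounded, logged), and observed yields carry multiplicative
    lognormal noise with the given CV — typical small-plot trial
    variability.
    """

    seed: int = 0
    yield_cv: float = 0.05                 # observation noise CV on yield
    mineralization_factor: float = 1.2     # truth / forecast ratio, in [0.8, 1.2]
    potential_yield_factor: float = 0.9    # truth / forecast ratio, in [0.8, 1.2]
    rotation: str = "continuous_corn"
    reference_n_rate: float = 134.0        # rate driving the carryover chain

    def __post_init__(self) -> None:
        if self.yield_cv < 0:
            raise ValueError("yield_cv must be >= 0")
        for name in ("mineralization_factor", "potential_yield_factor"):
            v = getattr(self, name)
            if not 0.8 <= v <= 1.2:
                raise ValueError(f"{name}={v} outside the bounded range [0.8, 1.2]")


@dataclass
class ObservedTruth:
    """Per-year observed response tables and EONRs, plus the starting soil."""

    study_years: tuple[int, ...]
    response_data: dict[int, NResponseData]
    eonr_results: dict[int, EonrResult]
    initial_soil: SoilState
    rotation: str

    @property
    def observed_eonr(self) -> dict[int, float]:
        return {y: r.eonr for y, r in self.eonr_results.items()}


def generate_observed_truth(
    lib: WeatherLibrary,
    study_years,
    cfg: TruthConfig | None = None,
    sim_cfg: SimConfig | None = None,
    mgmt_base: ManagementConfig | None = None,
    initial_soil: SoilState | None = None,
    n_rates=DEFAULT_N_RATES,
    price_ratio: float = DEFAULT_PRICE_RATIO,
) -> ObservedTruth:
    """Run the perturbed-truth experiment over the study years.

    Mirrors the forecasting protocol exactly: the soil state advances
    sequentially on the reference N rate with the year's full observed
    weather, and within each year all five rates start from that year's
    carried-over state. Each plot-year yield then receives multiplicative
    observation noise before the observed response is fitted and the
    observed EONR derived.
    """
    cfg = cfg or TruthConfig()
    sim_cfg = sim_cfg or SimConfig()
    mgmt_base = mgmt_base or ManagementConfig()
    initial_soil = initial_soil or default_initial_soil()
    study_years = tuple(sorted(int(y) for y in study_years))
    missing = [y for y in study_years if y not in lib]
    if missing:
        raise KeyError(f"study year(s) {missing} not in weather library")

    truth_sim = replace(
        sim_cfg,
        mineralization_rate=sim_cfg.mineralization_rate * cfg.mineralization_factor,
        potential_yield=sim_cfg.potential_yield * cfg.potential_yield_factor,
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rates = np.asarray(n_rates, dtype=float)

    response_data: dict[int, NResponseData] = {}
    eonr_results: dict[int, EonrResult] = {}
    soil = copy.deepcopy(initial_soil)
    for year in study_years:
        weather = lib[year]
        yields = np.empty_like(rates)
        for j, rate in enumerate(rates):
            mgmt = replace(mgmt_base, n_rate=float(rate), rotation=cfg.rotation)
            res = run_season(weather, mgmt, copy.deepcopy(soil), truth_sim)
            yields[j] = res.grain_yield
        if cfg.yield_cv > 0:
            sigma = np.sqrt(np.log(1.0 + cfg.yield_cv**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=yields.shape)
            yields = yields * noise
        data = NResponseData(rates, yields)
        eonr_res, _ = eonr_from_data(data, price_ratio, n_max=float(rates.max()))
        response_data[year] = data
        eonr_results[year] = eonr_res
        # advance the carryover chain on the reference rate
        mgmt = replace(mgmt_base, n_rate=cfg.reference_n_rate, rotation=cfg.rotation)
        soil = run_season(weather, mgmt, soil, truth_sim).end_soil_state
    return ObservedTruth(
        study_years=study_years,
        response_data=response_data,
        eonr_results=eonr_results,
        initial_soil=initial_soil,
        rotation=cfg.rotation,
    )
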