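"""A daily-timestep corn–soil nitrogen simulator.

This is a deliberately small process model, not a port of a full cropping
systems simulator. It keeps the minimum set of mechanisms that generate a
weather-by-nitrogen interaction in corn yield:

* a single-bucket soil water balance (rain, runoff, drainage above capacity,
  canopy-driven transpiration, bare-soil evaporation);
* a two-pool nitrogen balance: first-order mineralization of a soil organic
  pool and of surface residue (both modified by temperature and moisture),
  fertilizer additions, leaching proportional to drainage and to the
  inorganic-N pool, and crop uptake limited by daily access to inorganic N;
* growing-degree-day phenology (planting, V6, V12, R1, R6) with season
  failure if physiological maturity is not reached by year end;
* grain yield as potential yield scaled by the more limiting of a seasonal
  water-stress and nitrogen-stress index (law-of-the-minimum form), which
  produces a concave, plateauing yield response to fertilizer N.

Seasons chain: :func:`run_season` returns the end-of-year soil state so a
multi-year sequence can be simulated continuously without annual
re-initialization, carrying over residual water, inorganic and organic N and
surface residue. Soybean years in a soybean–corn rotation are not simulated
mechanistically; they act on the carried-over state through a fixed N credit
and a residue reduction.

Everything here is deterministic: identical inputs give bit-identical
results, which the ensemble machinery relies on.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .weather import DAYS_PER_YEAR, WeatherSeries

__all__ = [
    "SoilState",
    "ManagementConfig",
    "SimConfig",
    "SeasonResult",
    "SeasonFailureError",
    "accumulate_gdd",
    "stage_date",
    "run_season",
    "run_sequence",
    "default_initial_soil",
]

STAGES = ("planting", "V6", "V12", "R1", "R6")


class SeasonFailureError(RuntimeError):
    """A phenological stage target could not be reached within the year."""


@dataclass
class SoilState:
    """Carried-over soil pools at a season boundary.

    plant_available_water : mm, in [0, capacity]
    inorganic_n           : kg N/ha, plant-available mineral N
    organic_matter_n      : kg N/ha, slowly mineralizable organic pool
    surface_residue       : kg dry matter/ha on the surface
    """

    plant_available_water: float = 200.0
    inorganic_n: float = 20.0
    organic_matter_n: float = 9000.0
    surface_residue: float = 3000.0

    def validate(self, capacity: float) -> None:
        if not (0.0 <= self.plant_available_water <= capacity + 1e-9):
            raise ValueError(
                f"plant_available_water {self.plant_available_water} outside "
                f"[0, {capacity}]"
            )
        for name in ("inorganic_n", "organic_matter_n", "surface_residue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_initial_soil() -> SoilState:
    """Starting soil for a deep, fertile loam with 250 mm PAW capacity."""
    return SoilState()


@dataclass
class ManagementConfig:
    """Per-season management: planting, fertilizer, rotation, cultivar."""

    planting_doy: int = 120
    n_rate: float = 134.0  # kg N/ha
    n_application: str = "at_planting"  # or "side_dress"
    side_dress_doy: int | None = None
    rotation: str = "continuous_corn"  # or "soybean_corn"
    #: cumulative GDD (degC d, base temp) from planting to each stage
    gdd_targets: dict[str, float] = field(
        default_factory=lambda: {"V6": 280.0, "V12": 560.0, "R1": 760.0, "R6": 1250.0}
    )

    def __post_init__(self) -> None:
        t = self.gdd_targets
        order = [t[s] for s in ("V6", "V12", "R1", "R6")]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError(f"GDD targets must be non-decreasing V6<=V12<=R1<=R6: {t}")
        if self.n_application == "side_dress" and self.side_dress_doy is None:
            raise ValueError("side_dress application requires side_dress_doy")
        if self.rotation not in ("continuous_corn", "soybean_corn"):
            raise ValueError(f"unknown rotation {self.rotation!r}")

    @property
    def fertilizer_doy(self) -> int:
        if self.n_application == "side_dress":
            return int(self.side_dress_doy)  # type: ignore[arg-type]
        return self.planting_doy


@dataclass
class SimConfig:
    """Simulator parameters. Units in comments; defaults target a central-US
    Corn Belt loam and a ~13 Mg/ha potential corn crop."""

    base_temp: float = 10.0            # degC, GDD base
    potential_yield: float = 13000.0   # kg grain/ha at 15.5% moisture
    paw_capacity: float = 250.0        # mm, profile plant-available water
    runoff_threshold: float = 20.0     # mm/d, rain below this infiltrates fully
    runoff_coef: float = 0.5           # fraction of rain above threshold lost
    transp_coef: float = 0.17          # mm transpiration per MJ/m2 at full canopy
    evap_coef: float = 0.05            # mm soil evaporation per MJ/m2, bare soil
    extract_frac: float = 0.05         # 1/d, max fraction of PAW extractable
    mineralization_rate: float = 0.8e-4  # 1/d of organic pool at optimum T, W
    residue_decay_rate: float = 0.003  # 1/d of surface residue at optimum T, W
    residue_n_frac: float = 0.008      # kg N per kg residue dry matter
    residue_return: float = 4000.0     # kg DM/ha returned at corn maturity
    leaching_coef: float = 0.3         # scales drainage-driven leached fraction
    crop_n_demand: float = 230.0       # kg N/ha, season total at potential yield
    uptake_frac: float = 0.12          # 1/d, max fraction of inorganic N taken up
    stress_floor: float = 0.05         # lower bound on stress indices
    rotation_n_credit: float = 45.0    # kg N/ha added in a corn-after-soybean year
    soybean_residue_factor: float = 0.4  # residue multiplier after a soybean year

    def validate(self) -> None:
        if self.potential_yield <= 0:
            raise ValueError("potential_yield must be > 0")
        for name in (
            "paw_capacity", "runoff_coef", "transp_coef", "evap_coef",
            "extract_frac", "mineralization_rate", "residue_decay_rate",
            "leaching_coef", "crop_n_demand", "uptake_frac",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SeasonResult:
    """Outputs of one simulated season (one calendar year)."""

    grain_yield: float                     # kg/ha at 15.5% moisture
    stage_doys: dict[str, int | None]      # planting, V6, V12, R1, R6
    n_leached: float                       # kg N/ha
    crop_n_uptake: float                   # kg N/ha
    water_stress_index: float              # [0, 1]; 1 = no stress
    n_stress_index: float                  # [0, 1]; 1 = no stress
    end_soil_state: SoilState
    season_failed: bool = False
    # diagnostics for mass-balance audits
    n_fertilizer: float = 0.0
    n_credit: float = 0.0
    n_mineralized: float = 0.0
    precip_total: float = 0.0
    runoff_total: float = 0.0
    drainage_total: float = 0.0
    transpiration_total: float = 0.0
    evaporation_total: float = 0.0

    def n_balance_residual(self, soil0: SoilState) -> float:
        """Inputs minus outputs of the inorganic-N ledger (should be ~0)."""
        inputs = soil0.inorganic_n + self.n_fertilizer + self.n_credit + self.n_mineralized
        outputs = self.crop_n_uptake + self.n_leached + self.end_soil_state.inorganic_n
        return inputs - outputs

    def water_balance_residual(self, soil0: SoilState) -> float:
        inputs = soil0.plant_available_water + self.precip_total
        outputs = (
            self.runoff_total
            + self.drainage_total
            + self.transpiration_total
            + self.evaporation_total
            + self.end_soil_state.plant_available_water
        )
        return inputs - outputs


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------


def accumulate_gdd(
    weather: WeatherSeries, start_doy: int, base_temp: float = 10.0
) -> np.ndarray:
    """Cumulative growing degree days from ``start_doy`` through year end.

    ``out[i]`` is the GDD sum over days ``start_doy .. start_doy + i``
    (inclusive), with daily increments ``max(0, (tmax+tmin)/2 - base_temp)``.
    """
    if not 1 <= start_doy <= DAYS_PER_YEAR:
        raise ValueError(f"start_doy {start_doy} outside [1, {DAYS_PER_YEAR}]")
    inc = np.maximum(0.0, weather.tmean[start_doy - 1 :] - base_temp)
    return np.cumsum(inc)


def stage_date(
    weather: WeatherSeries,
    mgmt: ManagementConfig,
    stage: str,
    base_temp: float = 10.0,
) -> int:
    """First day-of-year at which cumulative GDD reaches the stage target.

    Thermal time accrues from the day after sowing, so a stage needing
    ``k`` average days lands ``k`` days after planting. Raises
    :class:`SeasonFailureError` if the target is not reached by day 365.
    """
    if stage == "planting":
        return mgmt.planting_doy
    if stage not in mgmt.gdd_targets:
        raise ValueError(f"unknown stage {stage!r}")
    target = mgmt.gdd_targets[stage]
    if mgmt.planting_doy >= DAYS_PER_YEAR:
        raise SeasonFailureError("planting on the last day leaves no season")
    cum = accumulate_gdd(weather, mgmt.planting_doy + 1, base_temp)
    idx = int(np.searchsorted(cum, target, side="left"))
    if target <= 0:
        return mgmt.planting_doy
    if idx >= cum.size or cum[idx] < target:
        raise SeasonFailureError(
            f"stage {stage} (GDD {target}) not reached by day {DAYS_PER_YEAR} "
            f"for year {weather.year_label}"
        )
    return mgmt.planting_doy + 1 + idx


# ---------------------------------------------------------------------------
# season engine
# ---------------------------------------------------------------------------


def run_season(
    weather: WeatherSeries,
    mgmt: ManagementConfig,
    soil0: SoilState,
    cfg: SimConfig | None = None,
) -> SeasonResult:
    """Simulate one calendar year and return yield, stages and end soil state.

    Soil water and nitrogen dynamics run over the whole year; the crop is
    present from planting to maturity (R6). If maturity is not reached by
    day 365 the season is flagged failed and yield is zero, but the soil
    state still advances so sequential runs never abort.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    soil0.validate(cfg.paw_capacity)

    # phenology first (independent of soil)
    stage_doys: dict[str, int | None] = {"planting": mgmt.planting_doy}
    failed = False
    for st in ("V6", "V12", "R1", "R6"):
        try:
            stage_doys[st] = stage_date(weather, mgmt, st, cfg.base_temp)
        except SeasonFailureError:
            stage_doys[st] = None
            failed = True
    r6_doy = stage_doys["R6"] or DAYS_PER_YEAR
    r1_target = mgmt.gdd_targets["R1"]
    r6_target = mgmt.gdd_targets["R6"]

    tmax = weather.tmax.tolist()
    tmin = weather.tmin.tolist()
    rain = weather.precip.tolist()
    radn = weather.radiation.tolist()

    paw = float(soil0.plant_available_water)
    inorg = float(soil0.inorganic_n)
    org = float(soil0.organic_matter_n)
    residue = float(soil0.surface_residue)

    n_credit = 0.0
    if mgmt.rotation == "soybean_corn":
        # carryover effect of the preceding soybean year, applied at Jan 1
        n_credit = cfg.rotation_n_credit
        inorg += n_credit
        residue *= cfg.soybean_residue_factor

    fert_doy = mgmt.fertilizer_doy
    fert_total = 0.0
    mineralized = 0.0
    leached = 0.0
    uptake = 0.0
    runoff_t = drain_t = transp_t = evap_t = 0.0
    pet_transp_t = 0.0
    demand_cum = 0.0

    capacity = cfg.paw_capacity
    gdd_cum = 0.0  # thermal time after planting
    plant_doy = mgmt.planting_doy

    for d in range(1, DAYS_PER_YEAR + 1):
        i = d - 1
        tmean = 0.5 * (tmax[i] + tmin[i])

        # thermal time and canopy (crop present after planting through R6)
        in_crop = plant_doy < d <= r6_doy
        if in_crop:
            gdd_cum += max(0.0, tmean - cfg.base_temp)
            fcan = min(1.0, gdd_cum / r1_target) if r1_target > 0 else 1.0
        else:
            fcan = 0.0

        # mineralization (temperature- and moisture-limited first order)
        ft = min(1.0, max(0.0, tmean / 25.0))
        fw = paw / capacity if capacity > 0 else 0.0
        mnrl = cfg.mineralization_rate * org * ft * fw
        org -= mnrl
        res_dec = cfg.residue_decay_rate * residue * ft * fw
        residue -= res_dec
        res_n = res_dec * cfg.residue_n_frac
        inorg += mnrl + res_n
        mineralized += mnrl + res_n

        # fertilizer
        if d == fert_doy:
            inorg += mgmt.n_rate
            fert_total += mgmt.n_rate

        # water balance
        p = rain[i]
        runoff = cfg.runoff_coef * max(0.0, p - cfg.runoff_threshold)
        paw += p - runoff
        drain = max(0.0, paw - capacity)
        paw -= drain
        runoff_t += runoff
        drain_t += drain

        pet_t = cfg.transp_coef * radn[i] * fcan
        pet_e = cfg.evap_coef * radn[i] * (1.0 - fcan)
        avail = cfg.extract_frac * paw
        transp = min(pet_t, avail)
        paw -= transp
        evap = min(pet_e, cfg.extract_frac * paw)
        paw -= evap
        transp_t += transp
        evap_t += evap
        if in_crop:
            pet_transp_t += pet_t

        # leaching: drainage carries a share of the inorganic pool
        if drain > 0.0 and inorg > 0.0:
            lfrac = min(1.0, cfg.leaching_coef * drain / capacity)
            loss = inorg * lfrac
            inorg -= loss
            leached += loss

        # crop N uptake: demand accrues with thermal time, catch-up allowed
        if in_crop:
            demand_cum = min(
                cfg.crop_n_demand,
                demand_cum + cfg.crop_n_demand * max(0.0, tmean - cfg.base_temp) / r6_target,
            )
            want = demand_cum - uptake
            if want > 0.0:
                take = min(want, cfg.uptake_frac * inorg)
                inorg -= take
                uptake += take

        # residue returned at maturity (stover left in the field)
        if not failed and d == r6_doy:
            residue += cfg.residue_return

    wsi = transp_t / pet_transp_t if pet_transp_t > 0 else 1.0
    nsi = uptake / demand_cum if demand_cum > 0 else 1.0
    wsi = min(1.0, max(cfg.stress_floor, wsi))
    nsi = min(1.0, max(cfg.stress_floor, nsi))

    grain_yield = 0.0 if failed else cfg.potential_yield * min(wsi, nsi)

    end_state = SoilState(
        plant_available_water=paw,
        inorganic_n=inorg,
        organic_matter_n=org,
        surface_residue=residue,
    )
    return SeasonResult(
        grain_yield=grain_yield,
        stage_doys=stage_doys,
        n_leached=leached,
        crop_n_uptake=uptake,
        water_stress_index=wsi,
        n_stress_index=nsi,
        end_soil_state=end_state,
        season_failed=failed,
        n_fertilizer=fert_total,
        n_credit=n_credit,
        n_mineralized=mineralized,
        precip_total=float(sum(rain)),
        runoff_total=runoff_t,
        drainage_total=drain_t,
        transpiration_total=transp_t,
        evaporation_total=evap_t,
    )


def run_sequence(
    years: list[tuple[WeatherSeries, ManagementConfig]],
    soil0: SoilState,
    cfg: SimConfig | None = None,
    reset_each_year: bool = False,
) -> list[SeasonResult]:
    """Simulate consecutive seasons, each starting from its predecessor's
    end-of-year soil state (or from ``soil0`` every year if
    ``reset_each_year``)."""
    if not years:
        raise ValueError("run_sequence needs at least one (weather, mgmt) pair")
    cfg = cfg or SimConfig()
    results: list[SeasonResult] = []
    state = copy.deepcopy(soil0)
    for weather, mgmt in years:
        start = copy.deepcopy(soil0) if reset_each_year else state
        res = run_season(weather, mgmt, start, cfg)
        results.append(res)
        state = res.end_soil_state
    return results
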