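"""Ensemble forecasting of yield and EONR by observed/historical weather splicing.

For one study year, one forecast time (a phenological stage), one analog
scenario and one rotation, :func:`forecast_cell` builds an ensemble of
weather realizations — observed weather up to the forecast time, one
historical donor year's weather thereafter — runs the crop simulator at
every N rate of the trial design for each member, fits a yield–N response
per member, and aggregates EONR / YEONR / yield distributions (mean and
sample SD across members).

Uncertainty collapses as the forecast time moves through the season: at
physiological maturity (R6) the whole season's weather is known, every
member is identical, and all ensemble SDs are exactly zero.

:func:`run_full_design` iterates the full factorial (rotations x study years
x forecast times x scenarios) with sequential soil carryover: within each
rotation, the soil state advances year to year on the *realized* (fully
observed) season at a fixed reference N rate, so every forecast cell of a
study year starts from the same soil state regardless of forecast time, and
forecasts never contaminate the carryover trajectory. A run ledger counts
simulator invocations.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cropsim import (
    ManagementConfig,
    SeasonResult,
    SimConfig,
    SoilState,
    default_initial_soil,
    run_season,
    stage_date,
)
from .response import (
    DEFAULT_N_RATES,
    DEFAULT_PRICE_RATIO,
    EonrResult,
    NResponseData,
    eonr_from_data,
)
from .weather import DAYS_PER_YEAR, WeatherLibrary, select_scenario_years, splice

__all__ = [
    "ForecastConfig",
    "MemberResult",
    "EnsembleForecast",
    "RunLedger",
    "SiteMeanSummary",
    "forecast_cell",
    "run_full_design",
    "site_mean",
    "members_frame",
    "cells_frame",
]

logger = logging.getLogger(__name__)

FORECAST_STAGES = ("planting", "V6", "V12", "R1", "R6")


@dataclass
class ForecastConfig:
    """The factorial forecast design and its shared parameters."""

    study_years: tuple[int, ...]
    forecast_times: tuple[str, ...] = ("planting", "V6", "V12", "R1")
    scenarios: tuple[str, ...] = ("full35",)
    n_rates: tuple[float, ...] = DEFAULT_N_RATES
    rotations: tuple[str, ...] = ("continuous_corn", "soybean_corn")
    price_ratio: float = DEFAULT_PRICE_RATIO
    random_seed: int = 0
    sequential_carryover: bool = True
    #: N rate used for the realized between-forecast carryover seasons
    reference_n_rate: float = 134.0

    def __post_init__(self) -> None:
        bad = [t for t in self.forecast_times if t not in FORECAST_STAGES]
        if bad:
            raise ValueError(f"unknown forecast time(s) {bad}; allowed {FORECAST_STAGES}")
        if len(set(self.n_rates)) < 4:
            raise ValueError("n_rates needs at least 4 distinct levels")


@dataclass
class MemberResult:
    """One ensemble member: the donor year, its yields, and its EONR."""

    donor_year: int
    yields: np.ndarray            # kg/ha, aligned with the design n_rates
    eonr_result: EonrResult | None
    failed: bool = False


@dataclass
class EnsembleForecast:
    """Aggregated forecast for one (year, forecast_time, scenario, rotation)."""

    year: int
    forecast_time: str
    scenario: str
    rotation: str
    splice_doy: int
    n_rates: tuple[float, ...]
    members: list[MemberResult]
    eonr_mean: float
    eonr_sd: float
    yeonr_mean: float
    yeonr_sd: float
    yield_mean: np.ndarray        # per N rate
    yield_sd: np.ndarray          # per N rate
    n_members: int                # scenario selection size
    n_failed: int

    def recompute_aggregates(self) -> dict[str, float | np.ndarray]:
        """Recompute the stored aggregates from the member results."""
        ok = [m for m in self.members if not m.failed] or self.members
        eonrs = np.array([m.eonr_result.eonr for m in ok])
        yeonrs = np.array([m.eonr_result.yeonr for m in ok])
        yields = np.vstack([m.yields for m in ok])
        return {
            "eonr_mean": _mean(eonrs),
            "eonr_sd": _sd(eonrs),
            "yeonr_mean": _mean(yeonrs),
            "yeonr_sd": _sd(yeonrs),
            "yield_mean": yields.mean(axis=0),
            "yield_sd": np.array([_sd(yields[:, j]) for j in range(yields.shape[1])]),
        }


@dataclass
class RunLedger:
    """Counts of simulator invocations in a full factorial design."""

    forecast_runs: int = 0        # members x rates, summed over cells
    carryover_runs: int = 0       # realized seasons advancing the soil chain
    failed_members: int = 0

    def add(self, other: "RunLedger") -> None:
        self.forecast_runs += other.forecast_runs
        self.carryover_runs += other.carryover_runs
        self.failed_members += other.failed_members


@dataclass(frozen=True)
class SiteMeanSummary:
    """Across-year (or pooled member-year) mean and SD of EONR and YEONR."""

    rotation: str
    source: str
    mean_eonr: float
    sd_eonr: float
    mean_yeonr: float
    sd_yeonr: float
    n_years: int


def _sd(x: np.ndarray) -> float:
    """Sample standard deviation; exactly 0 for identical values.

    The explicit identical-values guard matters: ``np.mean`` of n equal
    floats need not be exactly representable, which would otherwise turn an
    exactly-collapsed ensemble (all members saw the same weather) into a
    spurious ~1e-12 spread.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        return 0.0
    return float(np.std(x, ddof=1))


def _mean(x: np.ndarray) -> float:
    """Mean that returns the common value exactly when all values agree
    (``np.mean`` of n identical floats can be off by one ulp)."""
    x = np.asarray(x, dtype=float)
    if x.size and np.all(x == x[0]):
        return float(x[0])
    return float(x.mean())


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


def _splice_doy_for(
    forecast_time: str, observed, mgmt: ManagementConfig, base_temp: float
) -> int:
    """Day-of-year up to which weather is observed at the forecast time.

    Stage dates are computed from the study year's actual weather — what a
    forecaster standing at that stage would have seen. At R6 the full season
    is known, so the splice degenerates to the complete observed year.
    """
    if forecast_time == "planting":
        return mgmt.planting_doy
    if forecast_time == "R6":
        return DAYS_PER_YEAR
    return stage_date(observed, mgmt, forecast_time, base_temp)


def forecast_cell(
    cfg: ForecastConfig,
    year: int,
    forecast_time: str,
    scenario: str,
    rotation: str,
    lib: WeatherLibrary,
    soil_state: SoilState,
    sim_cfg: SimConfig | None = None,
    mgmt_base: ManagementConfig | None = None,
) -> tuple[EnsembleForecast, RunLedger]:
    """Forecast one (year x forecast_time x scenario x rotation) cell.

    All N rates of every member start from the same supplied ``soil_state``.
    Members whose season fails at any rate are flagged and excluded from the
    aggregates; the counts are reported on the result and the ledger.
    """
    sim_cfg = sim_cfg or SimConfig()
    mgmt_base = mgmt_base or ManagementConfig()
    observed = lib[year]
    donors = select_scenario_years(lib, year, scenario)
    if not donors:
        raise ValueError(
            f"scenario {scenario} selected no donor years for {year}"
        )
    splice_doy = _splice_doy_for(forecast_time, observed, mgmt_base, sim_cfg.base_temp)

    rates = np.asarray(cfg.n_rates, dtype=float)
    members: list[MemberResult] = []
    ledger = RunLedger()
    for donor in donors:
        series = splice(observed, lib[donor], splice_doy)
        yields = np.empty_like(rates)
        failed = False
        for j, rate in enumerate(rates):
            mgmt = replace(mgmt_base, n_rate=float(rate), rotation=rotation)
            res = run_season(series, mgmt, copy.deepcopy(soil_state), sim_cfg)
            ledger.forecast_runs += 1
            yields[j] = res.grain_yield
            failed = failed or res.season_failed
        if failed:
            ledger.failed_members += 1
        eonr_res, _ = eonr_from_data(
            NResponseData(rates, yields), cfg.price_ratio, n_max=float(rates.max())
        )
        members.append(MemberResult(donor, yields, eonr_res, failed=failed))

    ok = [m for m in members if not m.failed]
    if not ok:
        # a year in which no member matures (e.g. an extreme cold season):
        # aggregate the flagged members' zero-yield responses rather than
        # aborting, so the ensemble always reports a defined (flagged) value
        ok = members
    eonrs = np.array([m.eonr_result.eonr for m in ok])
    yeonrs = np.array([m.eonr_result.yeonr for m in ok])
    ymat = np.vstack([m.yields for m in ok])
    cell = EnsembleForecast(
        year=year,
        forecast_time=forecast_time,
        scenario=scenario,
        rotation=rotation,
        splice_doy=splice_doy,
        n_rates=tuple(float(r) for r in rates),
        members=members,
        eonr_mean=_mean(eonrs),
        eonr_sd=_sd(eonrs),
        yeonr_mean=_mean(yeonrs),
        yeonr_sd=_sd(yeonrs),
        yield_mean=ymat.mean(axis=0),
        yield_sd=np.array([_sd(ymat[:, j]) for j in range(ymat.shape[1])]),
        n_members=len(donors),
        n_failed=len(members) - len(ok),
    )
    return cell, ledger


# ---------------------------------------------------------------------------
# full design
# ---------------------------------------------------------------------------


def run_full_design(
    cfg: ForecastConfig,
    lib: WeatherLibrary,
    initial_soil: SoilState | None = None,
    sim_cfg: SimConfig | None = None,
    mgmt_base: ManagementConfig | None = None,
) -> tuple[list[EnsembleForecast], RunLedger]:
    """Run the full rotations x years x forecast-times x scenarios factorial.

    Within each rotation the soil state is advanced sequentially over the
    study years using the realized (fully observed) season at the reference
    N rate, unless ``cfg.sequential_carryover`` is off, in which case every
    year starts from ``initial_soil``.
    """
    sim_cfg = sim_cfg or SimConfig()
    mgmt_base = mgmt_base or ManagementConfig()
    initial_soil = initial_soil or default_initial_soil()

    cells: list[EnsembleForecast] = []
    ledger = RunLedger()
    for rotation in cfg.rotations:
        soil = copy.deepcopy(initial_soil)
        for year in sorted(cfg.study_years):
            for ft in cfg.forecast_times:
                for sc in cfg.scenarios:
                    cell, led = forecast_cell(
                        cfg, year, ft, sc, rotation, lib, soil, sim_cfg, mgmt_base
                    )
                    cells.append(cell)
                    ledger.add(led)
            logger.debug("forecast year %s rotation %s done", year, rotation)
            if cfg.sequential_carryover:
                mgmt = replace(
                    mgmt_base, n_rate=cfg.reference_n_rate, rotation=rotation
                )
                realized = run_season(lib[year], mgmt, soil, sim_cfg)
                ledger.carryover_runs += 1
                soil = realized.end_soil_state
    return cells, ledger


# ---------------------------------------------------------------------------
# summaries and export
# ---------------------------------------------------------------------------


def site_mean(
    values: np.ndarray | list[float],
    rotation: str = "",
    source: str = "",
    yeonr_values: np.ndarray | list[float] | None = None,
) -> SiteMeanSummary:
    """Unweighted mean and sample SD of annual (or pooled member-year) values.

    ``values`` are EONRs; optional ``yeonr_values`` are summarized alongside.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("site mean needs at least 2 values")
    if yeonr_values is None:
        ymean = ysd = float("nan")
    else:
        yv = np.asarray(yeonr_values, dtype=float)
        if yv.size != v.size:
            raise ValueError("yeonr_values length must match values")
        ymean, ysd = float(yv.mean()), _sd(yv)
    return SiteMeanSummary(
        rotation=rotation,
        source=source,
        mean_eonr=float(v.mean()),
        sd_eonr=_sd(v),
        mean_yeonr=ymean,
        sd_yeonr=ysd,
        n_years=int(v.size),
    )


def members_frame(cells: list[EnsembleForecast]) -> pd.DataFrame:
    """Tidy member-level results (one row per cell member)."""
    rows = []
    for c in cells:
        for m in c.members:
            row = {
                "year": c.year, "forecast_time": c.forecast_time,
                "scenario": c.scenario, "rotation": c.rotation,
                "donor_year": m.donor_year, "failed": m.failed,
            }
            for rate, y in zip(c.n_rates, m.yields):
                row[f"yield_{int(rate)}"] = y
            if m.eonr_result is not None:
                row["eonr"] = m.eonr_result.eonr
                row["yeonr"] = m.eonr_result.yeonr
                row["boundary_flag"] = m.eonr_result.boundary_flag
            rows.append(row)
    return pd.DataFrame(rows)


def cells_frame(cells: list[EnsembleForecast]) -> pd.DataFrame:
    """Tidy cell-level aggregates (one row per forecast cell)."""
    rows = []
    for c in cells:
        row = {
            "year": c.year, "forecast_time": c.forecast_time,
            "scenario": c.scenario, "rotation": c.rotation,
            "splice_doy": c.splice_doy, "n_members": c.n_members,
            "n_failed": c.n_failed,
            "eonr_mean": c.eonr_mean, "eonr_sd": c.eonr_sd,
            "yeonr_mean": c.yeonr_mean, "yeonr_sd": c.yeonr_sd,
        }
        for rate, m, s in zip(c.n_rates, c.yield_mean, c.yield_sd):
            row[f"yield_mean_{int(rate)}"] = m
            row[f"yield_sd_{int(rate)}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
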