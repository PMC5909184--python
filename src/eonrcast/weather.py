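"""Daily weather series: reading, validation, classification, analog selection, splicing.

A :class:`WeatherSeries` is one calendar year of daily weather on a fixed
365-day calendar (leap days are dropped on read so that day-of-year positions
align across years — a requirement for positional splicing of an observed
season with a historical one). A :class:`WeatherLibrary` is a collection of
such series, typically a multi-decade historical record, from which analog
years are selected to fill in the unknown remainder of a season being
forecast.

Five analog-selection scenarios are supported, mirroring common practice in
seasonal crop forecasting:

* ``"I"``   — years whose *annual* temperature/precipitation anomaly quadrant
  (warm/cold x wet/dry versus the library long-term mean) matches the target
  year's quadrant;
* ``"II"``  — same, using *summer* (June–August) anomalies;
* ``"III"`` / ``"IV"`` / ``"V"`` — the 5 / 10 / 20 calendar years immediately
  preceding the target year;
* ``"full35"`` — the entire library (the standard full-record approach).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "SUMMER_DOY_RANGE",
    "WeatherFormatError",
    "WeatherValidationError",
    "WeatherSeries",
    "WeatherLibrary",
    "YearClassification",
    "read_weather",
    "write_weather",
    "classify_year",
    "select_scenario_years",
    "splice",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365
#: day-of-year bounds (inclusive) of meteorological summer, Jun 1 – Aug 31,
#: on the 365-day (leap-normalized) calendar
SUMMER_DOY_RANGE = (152, 243)

CSV_COLUMNS = ["date", "tmax", "tmin", "precip", "radiation"]
MET_COLUMNS = ["year", "day", "radn", "maxt", "mint", "rain"]


class WeatherFormatError(ValueError):
    """A weather file does not conform to the expected dialect."""


class WeatherValidationError(ValueError):
    """Weather values violate physical invariants (with offending dates)."""


@dataclass(frozen=True)
class WeatherSeries:
    """One 365-day year of daily weather.

    Arrays are indexed by day-of-year minus one. ``provenance`` is one of
    ``"observed"``, ``"historical"`` or ``"spliced"``; a spliced series also
    records the splice day and the donor year label.
    """

    year_label: int
    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray
    radiation: np.ndarray
    provenance: str = "observed"
    splice_doy: int | None = None
    donor_label: int | None = None

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "precip", "radiation"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (DAYS_PER_YEAR,):
                raise WeatherValidationError(
                    f"{name} for year {self.year_label} has shape {arr.shape}, "
                    f"expected ({DAYS_PER_YEAR},)"
                )
            object.__setattr__(self, name, arr)
        bad = np.nonzero(self.tmax < self.tmin)[0]
        if bad.size:
            raise WeatherValidationError(
                f"tmax < tmin for year {self.year_label} on day(s) of year "
                f"{(bad + 1).tolist()}"
            )
        for name in ("precip", "radiation"):
            bad = np.nonzero(getattr(self, name) < 0)[0]
            if bad.size:
                raise WeatherValidationError(
                    f"negative {name} for year {self.year_label} on day(s) of "
                    f"year {(bad + 1).tolist()}"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def tmean(self) -> np.ndarray:
        return (self.tmax + self.tmin) / 2.0

    def annual_temp(self) -> float:
        """Mean daily temperature over the year (degC)."""
        return float(self.tmean.mean())

    def annual_precip(self) -> float:
        """Total precipitation over the year (mm)."""
        return float(self.precip.sum())

    def summer_temp(self) -> float:
        lo, hi = SUMMER_DOY_RANGE
        return float(self.tmean[lo - 1 : hi].mean())

    def summer_precip(self) -> float:
        lo, hi = SUMMER_DOY_RANGE
        return float(self.precip[lo - 1 : hi].sum())

    def to_frame(self) -> pd.DataFrame:
        doy = np.arange(1, DAYS_PER_YEAR + 1)
        offset = doy - 1
        if pd.Timestamp(f"{self.year_label}-01-01").is_leap_year:
            offset = np.where(doy >= 60, offset + 1, offset)  # skip Feb 29
        dates = pd.Timestamp(f"{self.year_label}-01-01") + pd.to_timedelta(
            offset, unit="D"
        )
        return pd.DataFrame(
            {
                "date": dates,
                "doy": doy,
                "tmax": self.tmax,
                "tmin": self.tmin,
                "precip": self.precip,
                "radiation": self.radiation,
            }
        )


@dataclass(frozen=True)
class YearClassification:
    """Anomaly-quadrant class of one year versus library long-term means."""

    year_label: int
    period: str  # "annual" | "summer"
    temp_class: str  # "warm" | "cold"
    precip_class: str  # "wet" | "dry"

    @property
    def quadrant(self) -> tuple[str, str]:
        return (self.temp_class, self.precip_class)


@dataclass
class WeatherLibrary:
    """A collection of :class:`WeatherSeries`, keyed by year label.

    Long-term statistics are always recomputed from the member series, never
    cached, so they stay consistent after mutation.
    """

    series: dict[int, WeatherSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.series = dict(sorted(self.series.items()))

    def __len__(self) -> int:
        return len(self.series)

    def __contains__(self, year: int) -> bool:
        return year in self.series

    def __getitem__(self, year: int) -> WeatherSeries:
        try:
            return self.series[year]
        except KeyError:
            raise KeyError(f"year {year} not in weather library") from None

    def add(self, s: WeatherSeries) -> None:
        self.series[s.year_label] = s
        self.series = dict(sorted(self.series.items()))

    @property
    def years(self) -> list[int]:
        return sorted(self.series)

    # -- long-term climatology ---------------------------------------------

    def mean_annual_precip(self) -> float:
        return float(np.mean([s.annual_precip() for s in self.series.values()]))

    def mean_annual_temp(self) -> float:
        return float(np.mean([s.annual_temp() for s in self.series.values()]))

    def mean_summer_precip(self) -> float:
        return float(np.mean([s.summer_precip() for s in self.series.values()]))

    def mean_summer_temp(self) -> float:
        return float(np.mean([s.summer_temp() for s in self.series.values()]))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _series_from_daily_frame(df: pd.DataFrame) -> list[WeatherSeries]:
    """Build per-year series from a frame with date/tmax/tmin/precip/radiation.

    Drops Feb 29, renumbers day-of-year onto the 365-day calendar, and demands
    complete gap-free years.
    """
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    leap = (df["date"].dt.month == 2) & (df["date"].dt.day == 29)
    if leap.any():
        logger.info("dropping %d leap day(s) (Feb 29)", int(leap.sum()))
        df = df[~leap]
    out: list[WeatherSeries] = []
    for year, grp in df.groupby(df["date"].dt.year):
        grp = grp.sort_values("date")
        # day-of-year on the 365-day calendar: post-Feb-29 days shift back one
        doy = grp["date"].dt.dayofyear.to_numpy()
        is_leap = pd.Timestamp(f"{year}-01-01").is_leap_year
        if is_leap:
            doy = np.where(doy > 59, doy - 1, doy)  # doy 60 was Feb 29
        if len(doy) != DAYS_PER_YEAR or not np.array_equal(
            doy, np.arange(1, DAYS_PER_YEAR + 1)
        ):
            missing = sorted(set(range(1, DAYS_PER_YEAR + 1)) - set(doy.tolist()))
            raise WeatherValidationError(
                f"year {year}: incomplete or non-contiguous daily record "
                f"({len(doy)} rows; missing day(s) of year {missing[:10]}...)"
            )
        try:
            out.append(
                WeatherSeries(
                    year_label=int(year),
                    tmax=grp["tmax"].to_numpy(float),
                    tmin=grp["tmin"].to_numpy(float),
                    precip=grp["precip"].to_numpy(float),
                    radiation=grp["radiation"].to_numpy(float),
                    provenance="historical",
                )
            )
        except WeatherValidationError as exc:
            # re-raise with calendar dates, which users can find in the file
            raise WeatherValidationError(f"year {year}: {exc}") from None
    return out


def read_weather(path: str | Path, dialect: str = "csv") -> WeatherLibrary:
    """Read a daily weather file into a :class:`WeatherLibrary`.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"csv"`` for the header ``date,tmax,tmin,precip,radiation`` (ISO
        dates), or ``"met"`` for the whitespace-separated APSIM met
        convention (``year day radn maxt mint rain`` with a
        ``[weather.met.weather]`` block and a units line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise WeatherFormatError(
                f"{path}: missing required column(s) {missing}; "
                f"expected header {','.join(CSV_COLUMNS)}"
            )
        frame = df[CSV_COLUMNS]
    elif dialect == "met":
        frame = _read_met(path)
    else:
        raise ValueError(f"unknown weather dialect {dialect!r}")
    lib = WeatherLibrary()
    for s in _series_from_daily_frame(frame):
        lib.add(s)
    return lib


def _read_met(path: Path) -> pd.DataFrame:
    header_cols: list[str] | None = None
    rows: list[list[float]] = []
    saw_section = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            if line.lower().startswith("[weather.met.weather]"):
                saw_section = True
                continue
            if "=" in line:  # site/latitude/tav/amp attribute lines
                continue
            toks = line.split()
            if header_cols is None:
                lowered = [t.lower() for t in toks]
                if "year" in lowered and "day" in lowered:
                    header_cols = lowered
                    continue
                raise WeatherFormatError(
                    f"{path}: expected met column header before data, got {line!r}"
                )
            if toks[0].startswith("("):  # units line
                continue
            rows.append([float(t) for t in toks])
    if not saw_section:
        raise WeatherFormatError(f"{path}: missing [weather.met.weather] section")
    if header_cols is None or not rows:
        raise WeatherFormatError(f"{path}: no data rows found")
    missing = [c for c in MET_COLUMNS if c not in header_cols]
    if missing:
        raise WeatherFormatError(f"{path}: missing met column(s) {missing}")
    df = pd.DataFrame(rows, columns=header_cols)
    date = pd.to_datetime(df["year"].astype(int) * 1000 + df["day"].astype(int),
                          format="%Y%j")
    return pd.DataFrame(
        {
            "date": date,
            "tmax": df["maxt"].astype(float),
            "tmin": df["mint"].astype(float),
            "precip": df["rain"].astype(float),
            "radiation": df["radn"].astype(float),
        }
    )


def write_weather(lib: WeatherLibrary, path: str | Path, dialect: str = "csv") -> None:
    """Write every series of a library to one file in the given dialect."""
    path = Path(path)
    frames = [lib[y].to_frame() for y in lib.years]
    df = pd.concat(frames, ignore_index=True)
    if dialect == "csv":
        out = df[["date", "tmax", "tmin", "precip", "radiation"]].copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
    elif dialect == "met":
        with open(path, "w") as fh:
            fh.write("[weather.met.weather]\n")
            fh.write("site = eonrcast synthetic\n")
            fh.write(f"tav = {lib.mean_annual_temp():.2f} (oC)\n")
            fh.write("year day radn maxt mint rain\n")
            fh.write("() () (MJ/m^2) (oC) (oC) (mm)\n")
            for _, r in df.iterrows():
                fh.write(
                    f"{r['date'].year} {int(r['date'].dayofyear)} {r['radiation']:.2f} "
                    f"{r['tmax']:.2f} {r['tmin']:.2f} {r['precip']:.2f}\n"
                )
    else:
        raise ValueError(f"unknown weather dialect {dialect!r}")


# ---------------------------------------------------------------------------
# classification and analog selection
# ---------------------------------------------------------------------------


def classify_year(
    lib: WeatherLibrary, year_label: int, period: str = "annual"
) -> YearClassification:
    """Assign a year to its warm/cold x wet/dry anomaly quadrant.

    The anomaly is taken against the library-wide long-term mean for the
    stated period (``"annual"`` or ``"summer"``). Exact ties resolve to
    warm / wet, so the four quadrants partition any library.
    """
    if year_label not in lib:
        raise KeyError(f"year {year_label} not in weather library")
    if len(lib) < 2:
        raise ValueError("library must contain at least 2 years to classify")
    s = lib[year_label]
    if period == "annual":
        t, p = s.annual_temp(), s.annual_precip()
        t_ref, p_ref = lib.mean_annual_temp(), lib.mean_annual_precip()
    elif period == "summer":
        t, p = s.summer_temp(), s.summer_precip()
        t_ref, p_ref = lib.mean_summer_temp(), lib.mean_summer_precip()
    else:
        raise ValueError(f"period must be 'annual' or 'summer', got {period!r}")
    return YearClassification(
        year_label=year_label,
        period=period,
        temp_class="warm" if t >= t_ref else "cold",
        precip_class="wet" if p >= p_ref else "dry",
    )


_PRIOR_YEAR_COUNTS = {"III": 5, "IV": 10, "V": 20}


def select_scenario_years(
    lib: WeatherLibrary, target_year: int, scenario: str
) -> list[int]:
    """Select the historical years an ensemble forecast will draw from.

    See the module docstring for scenario definitions. The target year never
    appears in its own analog set under scenarios I–V; the full-library
    baseline includes every year.
    """
    if target_year not in lib:
        raise KeyError(f"target year {target_year} not in weather library")
    if scenario == "full35":
        return lib.years
    if scenario in ("I", "II"):
        period = "annual" if scenario == "I" else "summer"
        target_q = classify_year(lib, target_year, period).quadrant
        return [
            y
            for y in lib.years
            if y != target_year and classify_year(lib, y, period).quadrant == target_q
        ]
    if scenario in _PRIOR_YEAR_COUNTS:
        k = _PRIOR_YEAR_COUNTS[scenario]
        prior = [y for y in lib.years if y < target_year]
        if len(prior) < k:
            raise ValueError(
                f"scenario {scenario} needs {k} years before {target_year}; "
                f"library has only {len(prior)}"
            )
        return prior[-k:]
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------


def splice(
    observed: WeatherSeries, donor: WeatherSeries, splice_doy: int
) -> WeatherSeries:
    """Combine observed weather up to ``splice_doy`` with donor weather after.

    The result equals ``observed`` for day-of-year <= ``splice_doy`` and
    ``donor`` for day-of-year > ``splice_doy``; its provenance records the
    splice day and the donor year.
    """
    if not 1 <= splice_doy <= DAYS_PER_YEAR:
        raise ValueError(
            f"splice_doy must be in [1, {DAYS_PER_YEAR}], got {splice_doy}"
        )
    k = int(splice_doy)

    def _mix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.concatenate([a[:k], b[k:]])

    return WeatherSeries(
        year_label=observed.year_label,
        tmax=_mix(observed.tmax, donor.tmax),
        tmin=_mix(observed.tmin, donor.tmin),
        precip=_mix(observed.precip, donor.precip),
        radiation=_mix(observed.radiation, donor.radiation),
        provenance="spliced",
        splice_doy=k,
        donor_label=donor.year_label,
    )
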