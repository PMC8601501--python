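"""Daily weather inputs: solar geometry, the Angstrom radiation estimate,
a seeded synthetic-season generator, and CSV / DSSAT-dialect file I/O.

Extraterrestrial radiation Ra and theoretical daylength N follow the FAO-56
solar-geometry formulas (inverse relative Earth-Sun distance, solar
declination, sunset hour angle).  Observed sunshine hours n convert to solar
radiation via the Angstrom equation Rs = (a + b * n/N) * Ra with the regional
coefficients a = 0.2, b = 0.5 by default.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1

CSV_COLUMNS = ["date", "tmax", "tmin", "rain", "sunshine_hours", "srad"]


@dataclass(frozen=True)
class AngstromCoefficients:
    """Regression coefficients of the Angstrom sunshine-to-radiation relation."""

    a: float = 0.2
    b: float = 0.5

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b > 1:
            raise ValueError("need a >= 0, b >= 0 and a + b <= 1")


class WeatherFormatError(ValueError):
    """A malformed weather file row; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(f"line {line}: {message}" if line is not None else message)
        self.line = line


def extraterrestrial_radiation(
    latitude: float, day_of_year: int
) -> tuple[float, float]:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1) and daylength N (h).

    Valid for |latitude| < 66.5 degrees (no polar day/night).
    """
    if abs(latitude) >= 66.5:
        raise ValueError("latitude must satisfy |lat| < 66.5 degrees")
    phi = math.radians(latitude)
    J = int(day_of_year)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * J / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * J / 365.0 - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(delta))))
    Ra = (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * math.sin(phi) * math.sin(delta)
           + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )
    N = 24.0 / math.pi * ws
    return max(Ra, 0.0), N


def angstrom_srad(
    sunshine_hours: float,
    N: float,
    Ra: float,
    coeffs: AngstromCoefficients = AngstromCoefficients(),
) -> float:
    """Estimated solar radiation Rs = (a + b * n/N) * Ra in MJ m-2 d-1."""
    if Ra < 0:
        raise ValueError("Ra must be non-negative")
    if not 0.0 <= sunshine_hours <= N + 1e-9:
        raise ValueError(
            f"sunshine hours {sunshine_hours} outside [0, daylength {N:.2f}]"
        )
    return (coeffs.a + coeffs.b * sunshine_hours / N) * Ra


def validate_daily(frame: pd.DataFrame) -> None:
    """Physical-consistency checks on a daily weather frame."""
    bad = frame.index[frame["tmax"] < frame["tmin"]]
    if len(bad):
        raise WeatherFormatError("tmax < tmin", line=int(bad[0]) + 2)
    if (frame["rain"] < 0).any():
        raise WeatherFormatError("negative rainfall")


def synth_weather(
    latitude: float,
    start: dt.date,
    n_days: int,
    mean_temp: float,
    season_rain: float,
    season_radiation: float,
    seed: int = 0,
    diurnal_range: float = 9.0,
    annual_amplitude: float = 11.0,
    wet_day_prob: float = 0.30,
) -> pd.DataFrame:
    """Generate a seeded synthetic daily series hitting seasonal summary targets.

    Temperature follows a sinusoidal annual cycle (coldest near mid-January in
    the northern hemisphere) plus day-to-day noise, shifted so the season mean
    equals ``mean_temp`` exactly.  Rain falls on seeded stochastic wet days
    with gamma-distributed amounts rescaled to ``season_rain``.  Radiation
    follows the clear-sky seasonal shape (0.55 * Ra) rescaled to
    ``season_radiation`` (treated as a season total).
    """
    if n_days < 1:
        raise ValueError("n_days must be positive")
    if season_rain < 0 or season_radiation <= 0:
        raise ValueError("season totals must be positive (rain may be zero)")
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime([start + dt.timedelta(days=i) for i in range(n_days)])
    doy = dates.dayofyear.to_numpy()
    # annual cycle: minimum around day 15 (mid-January) for the N hemisphere
    cycle = annual_amplitude * np.cos(2.0 * np.pi * (doy - 196) / 365.25)
    tmean = cycle + rng.normal(0.0, 1.8, n_days)
    tmean += mean_temp - tmean.mean()
    tmax = tmean + diurnal_range / 2.0
    tmin = tmean - diurnal_range / 2.0
    if season_rain == 0.0:
        rain = np.zeros(n_days)
    else:
        wet = rng.random(n_days) < wet_day_prob
        if not wet.any():
            wet[rng.integers(n_days)] = True
        amounts = np.where(wet, rng.gamma(0.8, 6.0, n_days), 0.0)
        rain = amounts * (season_rain / amounts.sum())
    ra_n = np.array([extraterrestrial_radiation(latitude, int(j)) for j in doy])
    srad_shape = 0.55 * ra_n[:, 0]
    srad = srad_shape * (season_radiation / srad_shape.sum())
    frame = pd.DataFrame(
        {
            "date": dates,
            "tmax": np.round(tmax, 2),
            "tmin": np.round(tmin, 2),
            "rain": np.round(rain, 3),
            "sunshine_hours": np.nan,
            "srad": np.round(srad, 3),
        }
    )
    # rounding nudges the totals; restore them exactly on the wettest/brightest
    # day so no value can go negative
    if season_rain > 0:
        iw = frame["rain"].idxmax()
        frame.loc[iw, "rain"] = round(
            frame.loc[iw, "rain"] + season_rain - frame["rain"].sum(), 6
        )
    ib = frame["srad"].idxmax()
    frame.loc[ib, "srad"] = round(
        frame.loc[ib, "srad"] + season_radiation - frame["srad"].sum(), 6
    )
    validate_daily(frame)
    return frame


def fill_srad(
    frame: pd.DataFrame,
    latitude: float,
    coeffs: AngstromCoefficients = AngstromCoefficients(),
) -> pd.DataFrame:
    """Fill missing srad from sunshine hours via the Angstrom equation."""
    frame = frame.copy()
    missing = frame["srad"].isna() & frame["sunshine_hours"].notna()
    for idx in frame.index[missing]:
        doy = int(pd.Timestamp(frame.loc[idx, "date"]).dayofyear)
        Ra, N = extraterrestrial_radiation(latitude, doy)
        frame.loc[idx, "srad"] = angstrom_srad(
            float(frame.loc[idx, "sunshine_hours"]), N, Ra, coeffs
        )
    return frame


def read_csv(path) -> pd.DataFrame:
    """Read a daily weather CSV with columns date,tmax,tmin,rain[,sunshine_hours,srad]."""
    frame = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "tmax", "tmin", "rain"} - set(frame.columns)
    if missing:
        raise WeatherFormatError(f"missing columns {sorted(missing)}")
    for col in ("sunshine_hours", "srad"):
        if col not in frame.columns:
            frame[col] = np.nan
    validate_daily(frame)
    return frame[CSV_COLUMNS]


def write_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, date_format="%Y-%m-%d")


def write_dssat(
    frame: pd.DataFrame,
    path,
    station: str = "SYNT",
    latitude: float = 0.0,
    longitude: float = 0.0,
    elevation: float = 0.0,
    coeffs: AngstromCoefficients = AngstromCoefficients(),
) -> None:
    """Write the DSSAT weather dialect (fixed-width daily records).

    Rows missing srad but carrying sunshine hours are filled via the
    Angstrom equation before writing; srad is mandatory in this dialect.
    """
    frame = fill_srad(frame, latitude, coeffs)
    if frame["srad"].isna().any():
        raise WeatherFormatError("srad missing and no sunshine hours to fill it")
    validate_daily(frame)
    lines = [
        f"*WEATHER DATA : {station}",
        "",
        "@ INSI      LAT     LONG  ELEV   TAV   AMP REFHT WNDHT",
        f"  {station:<4s} {latitude:8.3f} {longitude:8.3f} {elevation:5.0f} "
        f"{frame[['tmax', 'tmin']].to_numpy().mean():5.1f} "
        f"{(frame['tmax'] - frame['tmin']).mean():5.1f}   2.0   2.0",
        "@DATE  SRAD  TMAX  TMIN  RAIN",
    ]
    for _, row in frame.iterrows():
        ts = pd.Timestamp(row["date"])
        lines.append(
            f"{ts.strftime('%y%j')} {row['srad']:5.1f} {row['tmax']:5.1f} "
            f"{row['tmin']:5.1f} {row['rain']:5.1f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dssat(path) -> pd.DataFrame:
    """Read the DSSAT weather dialect written by :func:`write_dssat`."""
    rows = []
    with open(path) as fh:
        in_data = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("@DATE"):
                in_data = True
                continue
            if not in_data or not line.strip():
                continue
            try:
                date = dt.datetime.strptime(line[0:5], "%y%j").date()
                srad, tmax, tmin, rain = (float(x) for x in line[5:].split())
            except (ValueError, IndexError) as exc:
                raise WeatherFormatError(str(exc), line=lineno) from exc
            rows.append(
                {
                    "date": pd.Timestamp(date),
                    "tmax": tmax,
                    "tmin": tmin,
                    "rain": rain,
                    "sunshine_hours": np.nan,
                    "srad": srad,
                }
            )
    if not rows:
        raise WeatherFormatError("no daily records found")
    frame = pd.DataFrame(rows)
    validate_daily(frame)
    return frame
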