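"""A self-contained daily rapeseed growth surrogate.

This is deliberately NOT a reimplementation of any production crop model: it
is a minimal, fully documented daily model exposing the same 35-parameter
interface (12 ecotype, 11 genotype, 12 soil inputs) and the same five season
outputs (ADAP, MDAP, HWAM, CWAM, LAIX), with a designed causal structure so
that the sensitivity-analysis and calibration machinery can be exercised and
tested end to end without an external simulator.

Model sketch
------------
Phenology is driven by thermal time with base temperature 5 degC and an
optimum scale of 15 degC (one "thermal day" accrues at a daily mean of
20 degC).  Progress toward flowering is a photothermal day: the thermal day
times a long-day photoperiod factor (slowed when daylength is below CSDL,
sensitivity increased by R1PPO after flowering) times a cold penalty (slowed
when TMIN is below OPTBI with slope SLOBI).  Stages: emergence after PL-EM
thermal days; first leaf EM-V1 and floral induction JU-R0 later; anthesis
when EM-FL photothermal days accrue; physiological maturity after
FL-SD + SD-PM (shaped by PM09 and LNGSH) reproductive photothermal days;
harvest maturity after R7-R8 further thermal days.

Leaf area grows with the main-stem leaf appearance rate TRIFL, leaf size
SIZLF and specific leaf area SLAVR until FL-LF after flowering, then
senesces.  Daily biomass is radiation-use efficiency times intercepted PAR
(canopy extinction shaped by RWDTH/RHGHT) times temperature and water stress
factors.  Water comes from a layered tipping-bucket balance: plant-available
capacity SDUL-SLLL, saturation SSAT, drainage SLDR (limited by SSKS), curve
number runoff SLRO, stage-one evaporation limit SLU1, root access SRGF.
SALB, SLOC, SBDM and SLNF enter as weak modifiers of evaporation and
radiation-use efficiency so that every sampled factor is a live input.
Yield accumulates from biomass gained during seed filling with a
partitioning coefficient shaped by PODUR, SFDUR and SDPDV.

A small unconditional daily increment (0.05) keeps development moving even
through deep cold so that extreme parameter corners still mature inside a
generous weather window.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .evaluation import SeasonRecord
from .parameters import load_soil_profile
from .weather import extraterrestrial_radiation, synth_weather

BASE_TEMP = 5.0  # degC, thermal-time base for rapeseed
TEMP_SCALE = 15.0  # degC above base giving one full thermal day
DEV_FLOOR = 0.05  # unconditional daily development increment
PHOTOPERIOD_SLOPE = 0.015  # per hour of daylength deficit below CSDL
COLD_SLOPE = 0.014  # per degC of TMIN deficit at the nominal SLOBI (0.035)

PARAMETER_NAMES = [
    "PL-EM", "EM-V1", "JU-R0", "PM09", "LNGSH", "R7-R8", "TRIFL", "RWDTH",
    "RHGHT", "R1PPO", "OPTBI", "SLOBI", "CSDL", "EM-FL", "FL-SH", "FL-SD",
    "SD-PM", "FL-LF", "SLAVR", "SIZLF", "SFDUR", "SDPDV", "PODUR", "SLLL",
    "SDUL", "SSAT", "SRGF", "SSKS", "SBDM", "SLOC", "SALB", "SLU1", "SLDR",
    "SLRO", "SLNF",
]


class SeasonWindowError(RuntimeError):
    """The weather series ended before the crop reached harvest maturity."""


@lru_cache(maxsize=None)
def _daylength(latitude: float, day_of_year: int) -> float:
    return extraterrestrial_radiation(latitude, day_of_year)[1]


@dataclass(frozen=True)
class Management:
    sowing_date: dt.date
    population: float = 45.0  # plants m-2
    latitude: float = 30.47


@dataclass(frozen=True)
class SeasonOutputs:
    ADAP: int  # days sowing -> anthesis
    MDAP: int  # days sowing -> harvest maturity
    HWAM: float  # yield, kg/ha
    CWAM: float  # above-ground biomass at maturity, kg/ha
    LAIX: float  # maximum leaf area index

    def __post_init__(self) -> None:
        if not 0 < self.ADAP < self.MDAP:
            raise ValueError("need 0 < ADAP < MDAP")
        if not 0.0 <= self.HWAM <= self.CWAM + 1e-9:
            raise ValueError("need 0 <= HWAM <= CWAM")
        if self.LAIX < 0:
            raise ValueError("LAIX must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "ADAP": self.ADAP, "MDAP": self.MDAP, "HWAM": self.HWAM,
            "CWAM": self.CWAM, "LAIX": self.LAIX,
        }


def _soil_layers(profile: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Layer thicknesses (cm) and root-shape weights from a soil profile table."""
    depths = profile["depth_cm"].to_numpy(dtype=float)
    if not np.all(np.diff(depths) > 0):
        raise ValueError("soil profile depths must be strictly increasing")
    thickness = np.diff(np.concatenate([[0.0], depths]))
    shape = profile["srgf"].to_numpy(dtype=float)
    return thickness, shape


def _validate_soil(params: dict[str, float]) -> None:
    if not params["SLLL"] < params["SDUL"] < params["SSAT"]:
        raise ValueError("soil water limits must satisfy SLLL < SDUL < SSAT")


def simulate_season(
    params: dict[str, float],
    weather: pd.DataFrame,
    soil_profile: pd.DataFrame | None = None,
    management: Management | None = None,
) -> SeasonOutputs:
    """Run one season of the surrogate and return its five outputs.

    ``weather`` is a daily frame (date, tmax, tmin, rain, srad) starting on
    the sowing day and covering the whole season; a window that ends before
    harvest maturity raises :class:`SeasonWindowError`.
    """
    p = {name: float(params[name]) for name in PARAMETER_NAMES}
    _validate_soil(p)
    management = management or Management(
        sowing_date=pd.Timestamp(weather["date"].iloc[0]).date()
    )
    if soil_profile is None:
        soil_profile = load_soil_profile()
    thickness, root_shape = _soil_layers(soil_profile)

    tmax = weather["tmax"].to_numpy(dtype=float)
    tmin = weather["tmin"].to_numpy(dtype=float)
    rain = weather["rain"].to_numpy(dtype=float)
    srad = weather["srad"].to_numpy(dtype=float)
    n_days = len(weather)
    doy = pd.DatetimeIndex(weather["date"]).dayofyear.to_numpy()
    daylength = np.array(
        [_daylength(management.latitude, int(j)) for j in doy]
    )
    tmean = 0.5 * (tmax + tmin)

    # development rates (precomputable: no feedback from crop state)
    tt = np.clip((tmean - BASE_TEMP) / TEMP_SCALE, 0.0, 1.2)
    cold = np.clip(
        1.0
        - (p["SLOBI"] / 0.035) * COLD_SLOPE * np.maximum(0.0, p["OPTBI"] - tmin),
        0.4, 1.0,
    )
    deficit = np.maximum(0.0, p["CSDL"] - daylength)
    photo_veg = np.clip(1.0 - PHOTOPERIOD_SLOPE * deficit, 0.6, 1.0)
    photo_rep = np.clip(
        1.0 - PHOTOPERIOD_SLOPE * (1.0 + p["R1PPO"]) * deficit, 0.5, 1.0
    )
    thermal_day = DEV_FLOOR + (1.0 - DEV_FLOOR) * tt
    ptd_veg = DEV_FLOOR + (1.0 - DEV_FLOOR) * tt * photo_veg * cold
    ptd_rep = DEV_FLOOR + (1.0 - DEV_FLOOR) * tt * photo_rep * cold

    def crossing(rates: np.ndarray, start: int, threshold: float) -> int:
        cum = np.cumsum(rates[start:])
        hit = np.searchsorted(cum, threshold)
        if hit >= len(cum):
            raise SeasonWindowError(
                f"weather window ({n_days} d) too short: development threshold "
                f"{threshold:.2f} not reached"
            )
        return start + int(hit)

    emergence = crossing(thermal_day, 0, p["PL-EM"])
    first_leaf = crossing(thermal_day, emergence, p["EM-V1"])
    induction = crossing(thermal_day, emergence, p["JU-R0"])
    anthesis = crossing(ptd_veg, induction, p["EM-FL"])
    leaf_stop = crossing(ptd_rep, anthesis, p["FL-LF"])
    # reproductive span: first seed plus seed-to-maturity, shaped by the
    # late-seed window PM09 and shell growth time LNGSH
    rep_span = (
        p["FL-SD"]
        + p["SD-PM"] * (1.0 + 0.3 * (p["PM09"] - 0.355))
        + 0.25 * p["LNGSH"]
    )
    first_pod = crossing(ptd_rep, anthesis, p["FL-SH"])
    first_seed = crossing(ptd_rep, anthesis, p["FL-SD"])
    phys_maturity = crossing(ptd_rep, anthesis, rep_span)
    harvest = crossing(thermal_day, phys_maturity, p["R7-R8"])

    # --- daily leaf-area / water / carbon loop -------------------------------
    dul, lll, sat = p["SDUL"], p["SLLL"], p["SSAT"]
    cap_mm = (dul - lll) * thickness * 10.0  # plant-available per layer, mm
    sat_mm = (sat - lll) * thickness * 10.0
    water = 0.5 * cap_mm  # sowing after a half-depleted summer profile
    root_w = np.clip(root_shape * p["SRGF"], 0.0, 1.0)
    drain_frac = p["SLDR"]
    perc_cap = p["SSKS"] * 240.0  # cm/h -> mm/day
    cn = p["SLRO"]
    s_ret = 25.4 * (1000.0 / cn - 10.0)
    k_ext = 0.32 * (0.8 + 0.2 * p["RWDTH"]) * (0.95 + 0.05 * p["RHGHT"])
    rue = (
        1.15
        * (0.85 + 0.15 * p["SLNF"])
        * (1.0 + 0.012 * (p["SLOC"] - 2.674))
        * (1.2 / p["SBDM"]) ** 0.05
    )  # g biomass per MJ PAR
    sla_factor = p["SLAVR"] / 237.5
    lai_cap = 6.0 * sla_factor
    leaf_scale = 0.5  # keeps canopy cover off its saturation plateau
    pod_frac = (
        0.55
        * (10.0 / p["PODUR"]) ** 0.4
        * (p["SFDUR"] / 20.0) ** 0.2
        * (p["SDPDV"] / 20.0) ** 0.1
    )
    pod_frac = min(pod_frac, 0.85)

    lai = 0.0
    laix = 0.0
    biomass = 0.0  # g/m2
    grain = 0.0
    for d in range(emergence, harvest + 1):
        # potential evapotranspiration proxy (Hargreaves-flavoured)
        et0 = max(0.0, 0.016 * srad[d] * (tmean[d] + 15.0))
        cover = 1.0 - math.exp(-k_ext * lai)
        # water balance: runoff, infiltration, drainage, evaporation, uptake
        pr = rain[d]
        runoff = 0.0
        if pr > 0.2 * s_ret:
            runoff = (pr - 0.2 * s_ret) ** 2 / (pr + 0.8 * s_ret)
        infil = pr - runoff
        for layer in range(len(water)):
            room = sat_mm[layer] - water[layer]
            added = min(infil, room)
            water[layer] += added
            infil -= added
            if infil <= 0:
                break
        excess = np.maximum(water - cap_mm, 0.0)
        drain = np.minimum(excess * drain_frac, perc_cap)
        water -= drain
        water[1:] += drain[:-1]  # percolates into the next layer; bottom is lost
        np.minimum(water, sat_mm, out=water)
        e_pot = min((1.0 - cover) * et0 * (1.0 - p["SALB"]), 0.35 * p["SLU1"])
        e_act = min(e_pot, water[0])
        water[0] -= e_act
        t_pot = cover * et0
        avail = water * root_w
        supply = 0.10 * avail.sum()
        stress = 1.0 if t_pot <= 1e-9 else min(1.0, supply / t_pot)
        uptake = min(t_pot, supply)
        if avail.sum() > 1e-9:
            water -= uptake * avail / avail.sum()
        # canopy development
        if first_leaf <= d <= leaf_stop:
            # branching makes canopy build-up superlinear in the main-stem
            # leaf appearance rate
            dv = (p["TRIFL"] ** 2 / 0.32) * tt[d]
            dlai = (
                leaf_scale * dv * p["SIZLF"] * sla_factor
                * management.population * 1e-4
                * (0.5 + 0.5 * stress)
                * max(0.0, 1.0 - lai / lai_cap)
            )
            lai += dlai
        elif d > leaf_stop:
            lai *= 0.97
        laix = max(laix, lai)
        # carbon: assimilation stops at physiological maturity
        dbio = 0.0
        if d <= phys_maturity:
            dbio = rue * 0.5 * srad[d] * cover * tt[d] * stress
        biomass += dbio
        if first_pod <= d < first_seed:
            grain += 0.3 * pod_frac * dbio  # pod walls before seeds set
        elif first_seed <= d <= phys_maturity:
            grain += pod_frac * dbio
    grain = min(grain, biomass)
    return SeasonOutputs(
        ADAP=anthesis,
        MDAP=harvest,
        HWAM=round(grain * 10.0, 1),  # g/m2 -> kg/ha
        CWAM=round(biomass * 10.0, 1),
        LAIX=round(laix, 3),
    )


def default_parameters() -> dict[str, float]:
    """Mid-range defaults, overridden by the published cultivar defaults
    for the five calibrated coefficients (EM-FL 29, OPTBI 20, SLOBI 0.035,
    SLAVR 250, TRIFL 0.32)."""
    from .parameters import load_calibrated_coefficients, load_parameter_specs

    values = {s.name: s.midpoint for s in load_parameter_specs()}
    for _, row in load_calibrated_coefficients().iterrows():
        values[row["name"]] = float(row["default"])
    return values


def wuhan_weather(
    year: int = 2018,
    seed: int = 0,
    n_days: int = 540,
    sowing: dt.date | None = None,
) -> tuple[pd.DataFrame, Management]:
    """Synthetic Wuhan-like season weather plus matching management."""
    sowing = sowing or dt.date(year, 9, 28)
    frame = synth_weather(
        latitude=30.47,
        start=sowing,
        n_days=n_days,
        mean_temp=17.4,
        season_rain=530.6 * n_days / 240.0,
        season_radiation=2162.4 * n_days / 240.0,
        seed=seed,
    )
    return frame, Management(sowing_date=sowing, latitude=30.47)


def make_efast_adapter(
    weather: pd.DataFrame,
    soil_profile: pd.DataFrame | None = None,
    management: Management | None = None,
    base_params: dict[str, float] | None = None,
):
    """Model adapter for the EFAST pipeline: parameter dict -> 5 outputs.

    Sampled values overlay ``base_params`` (the cultivar defaults unless
    given), so designs over a parameter subset hold the rest fixed.
    """
    base = dict(base_params) if base_params is not None else default_parameters()

    def adapter(params: dict[str, float]) -> dict[str, float]:
        full = {**base, **params}
        return simulate_season(full, weather, soil_profile, management).as_dict()

    return adapter


def make_calibration_model(
    weathers: list[pd.DataFrame],
    managements: list[Management],
    soil_profile: pd.DataFrame | None = None,
):
    """Model adapter for the calibration objective.

    Returns ``model(candidate, season)`` where the season is matched to its
    weather series by sowing date.
    """
    by_sowing = {
        m.sowing_date: (w, m) for w, m in zip(weathers, managements)
    }

    def model(candidate: dict[str, float], season: SeasonRecord) -> dict[str, float]:
        weather, mgmt = by_sowing[season.sowing_date]
        out = simulate_season(candidate, weather, soil_profile, mgmt)
        return {
            "anthesis_dap": out.ADAP,
            "maturity_dap": out.MDAP,
            "yield": out.HWAM,
            "biomass": out.CWAM,
        }

    return model


def generate_observations(
    true_params: dict[str, float],
    n_seasons: int = 5,
    phenology_sd: float = 0.0,
    biomass_cv: float = 0.0,
    seed: int = 0,
    start_year: int = 2014,
    noise_seed: int | None = None,
) -> tuple[list[SeasonRecord], list[pd.DataFrame], list[Management]]:
    """Synthetic observed seasons: surrogate outputs plus seeded noise.

    ``phenology_sd`` is Gaussian noise in days on anthesis/maturity dates,
    ``biomass_cv`` a relative (fractional) noise on yield and biomass.  With
    both zero the records equal the surrogate outputs exactly.  ``seed``
    fixes the seasons' weather; ``noise_seed`` (defaulting to ``seed``)
    fixes the measurement noise, so noise replicates of the same seasons
    use one ``seed`` with varying ``noise_seed``.
    """
    if phenology_sd < 0 or biomass_cv < 0:
        raise ValueError("noise levels must be non-negative")
    rng = np.random.default_rng(seed if noise_seed is None else noise_seed)
    records, weathers, managements = [], [], []
    for i in range(n_seasons):
        weather, mgmt = wuhan_weather(year=start_year + i, seed=seed * 1000 + i)
        out = simulate_season(true_params, weather, management=mgmt)
        adap = out.ADAP + (
            int(round(rng.normal(0.0, phenology_sd))) if phenology_sd else 0
        )
        mdap = out.MDAP + (
            int(round(rng.normal(0.0, phenology_sd))) if phenology_sd else 0
        )
        mdap = max(mdap, adap + 1)
        hwam = out.HWAM * (1.0 + (rng.normal(0.0, biomass_cv) if biomass_cv else 0.0))
        cwam = out.CWAM * (1.0 + (rng.normal(0.0, biomass_cv) if biomass_cv else 0.0))
        records.append(
            SeasonRecord(
                sowing_date=mgmt.sowing_date,
                obs_anthesis=mgmt.sowing_date + dt.timedelta(days=max(adap, 1)),
                obs_maturity=mgmt.sowing_date + dt.timedelta(days=mdap),
                obs_yield=max(hwam, 0.0),
                obs_biomass=max(cwam, hwam, 0.0),
            )
        )
        weathers.append(weather)
        managements.append(mgmt)
    return records, weathers, managements
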