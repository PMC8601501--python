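"""Calibration/evaluation statistics for paired observed vs simulated seasons.

Statistics follow the usual crop-model evaluation conventions:

    RMSE  = sqrt( sum (P - O)^2 / N )          (native units)
    nRMSE = 100 * RMSE / mean(O)               (%)
    ME    = sum (P - O) / N                    (signed, simulated - observed)
    rME   = 100 * ME / mean(O)                 (%)
    d     = 1 - sum (P-O)^2 / sum (|P - Obar| + |O - Obar|)^2   (Willmott)

Phenology statistics are computed on days after planting (DAP), never on
calendar ordinals, so that sowing-date differences between seasons do not
leak into the errors.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeasonRecord:
    """Observed and simulated outcomes for one growing season."""

    sowing_date: dt.date
    obs_anthesis: dt.date
    obs_maturity: dt.date
    obs_yield: float
    obs_biomass: float
    sim_anthesis: dt.date | None = None
    sim_maturity: dt.date | None = None
    sim_yield: float | None = None
    sim_biomass: float | None = None

    def __post_init__(self) -> None:
        if self.obs_anthesis <= self.sowing_date:
            raise ValueError("anthesis must fall after sowing")
        if self.obs_maturity <= self.obs_anthesis:
            raise ValueError("maturity must fall after anthesis")
        if self.obs_yield < 0 or self.obs_biomass < 0:
            raise ValueError("yield and biomass must be non-negative")

    @property
    def obs_anthesis_dap(self) -> int:
        return days_after_planting(self.sowing_date, self.obs_anthesis)

    @property
    def obs_maturity_dap(self) -> int:
        return days_after_planting(self.sowing_date, self.obs_maturity)


@dataclass(frozen=True)
class EvalStats:
    N: int
    RMSE: float
    nRMSE: float  # percent
    ME: float
    rME: float  # percent
    d: float


def days_after_planting(sowing: dt.date, event: dt.date) -> int:
    """Exact calendar-day count from sowing to an event (leap years honoured)."""
    if event < sowing:
        raise ValueError(f"event {event} precedes sowing {sowing}")
    return (event - sowing).days


def fit_statistics(observed, simulated) -> EvalStats:
    """RMSE, nRMSE, ME, rME and Willmott's d for paired series.

    ``observed`` and ``simulated`` must be equal-length numeric sequences;
    mean(observed) must be non-zero for the relative measures.
    """
    O = np.asarray(observed, dtype=float)
    P = np.asarray(simulated, dtype=float)
    if O.shape != P.shape or O.ndim != 1:
        raise ValueError("observed and simulated must be equal-length 1-d series")
    if len(O) < 1:
        raise ValueError("need at least one pair")
    N = len(O)
    err = P - O
    rmse = math.sqrt(float(np.mean(err**2)))
    me = float(np.mean(err))
    obar = float(np.mean(O))
    if obar == 0.0:
        raise ZeroDivisionError("mean of observations is zero; nRMSE/rME undefined")
    sq_num = float(np.sum(err**2))
    sq_den = float(np.sum((np.abs(P - obar) + np.abs(O - obar)) ** 2))
    if sq_den == 0.0:
        d = 1.0 if sq_num == 0.0 else 0.0
    else:
        d = 1.0 - sq_num / sq_den
    return EvalStats(
        N=N,
        RMSE=rmse,
        nRMSE=100.0 * rmse / obar,
        ME=me,
        rME=100.0 * me / obar,
        d=d,
    )


def relative_errors(rmse: float, me: float, observed_mean: float) -> tuple[float, float]:
    """nRMSE and rME (%) from absolute RMSE/ME and the observed mean.

    The normalisation step on its own, for when published absolute errors are
    combined with observed series to audit printed relative statistics.
    """
    if observed_mean == 0.0:
        raise ZeroDivisionError("observed mean is zero")
    return 100.0 * rmse / observed_mean, 100.0 * me / observed_mean


DEFAULT_OBJECTIVE_WEIGHTS = {
    "anthesis": 1.0,
    "maturity": 1.0,
    "yield": 1.0,
    "biomass": 1.0,
}


def calibration_objective(
    candidate: dict[str, float],
    seasons: list[SeasonRecord],
    model,
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted nRMSE loss of a candidate parameter set over observed seasons.

    ``model(candidate, season)`` must return a dict with keys
    ``anthesis_dap, maturity_dap, yield, biomass`` (simulated values for that
    season).  Model failure on any season yields an infinite loss.
    """
    weights = weights or DEFAULT_OBJECTIVE_WEIGHTS
    sims: dict[str, list[float]] = {k: [] for k in weights}
    obs: dict[str, list[float]] = {k: [] for k in weights}
    for season in seasons:
        try:
            sim = model(candidate, season)
        except Exception:
            logger.warning("model failed for candidate %s; infinite loss", candidate)
            return math.inf
        if not all(np.isfinite(list(sim.values()))):
            logger.warning("non-finite simulation for candidate %s", candidate)
            return math.inf
        sims["anthesis"].append(sim["anthesis_dap"])
        sims["maturity"].append(sim["maturity_dap"])
        sims["yield"].append(sim["yield"])
        sims["biomass"].append(sim["biomass"])
        obs["anthesis"].append(season.obs_anthesis_dap)
        obs["maturity"].append(season.obs_maturity_dap)
        obs["yield"].append(season.obs_yield)
        obs["biomass"].append(season.obs_biomass)
    loss = 0.0
    for key, w in weights.items():
        stats = fit_statistics(obs[key], sims[key])
        loss += w * stats.nRMSE
    return loss


def grid_search(
    name: str,
    grid,
    base: dict[str, float],
    seasons: list[SeasonRecord],
    model,
    weights: dict[str, float] | None = None,
) -> tuple[float, dict[float, float]]:
    """One-dimensional grid search over a single calibrated parameter.

    Returns the best grid value and the full value -> loss map; ties break
    toward the smaller parameter value (grid order).
    """
    losses: dict[float, float] = {}
    for value in grid:
        candidate = dict(base)
        candidate[name] = float(value)
        losses[float(value)] = calibration_objective(
            candidate, seasons, model, weights=weights
        )
    best = min(losses, key=lambda v: (losses[v], v))
    return best, losses
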