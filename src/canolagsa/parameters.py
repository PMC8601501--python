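"""Model input parameters and packaged reference tables.

The sensitivity study varies 35 inputs of the rapeseed growth model:
12 ecotype coefficients, 11 genotype (cultivar) coefficients and 12 soil
parameters, each sampled uniformly within an agronomically plausible range.
The ranges ship with the package as a plain-text table, together with the
site summaries, soil profile, observed seasons and calibrated cultivar
coefficients used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

VALID_GROUPS = frozenset({"ecotype", "genotype", "soil"})


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its sampling range.

    Parameters are sampled uniformly on ``[lower, upper]`` in native units.
    ``group`` classifies the input as an ecotype, genotype or soil parameter.
    """

    name: str
    lower: float
    upper: float
    group: str = "genotype"
    definition: str = ""
    distribution: str = field(default="uniform", compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("parameter name must be non-empty")
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.name}: lower bound {self.lower} must be < upper {self.upper}"
            )
        if self.group not in VALID_GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")
        if self.distribution != "uniform":
            raise ValueError("only uniform sampling is supported")

    @property
    def span(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


def _data_path(name: str):
    return resources.files("canolagsa.data").joinpath(name)


def load_parameter_table() -> pd.DataFrame:
    """The packaged 35-parameter range table (name, definition, lower, upper, group)."""
    with resources.as_file(_data_path("parameter_ranges.csv")) as p:
        return pd.read_csv(p)


def load_parameter_specs(groups: list[str] | None = None) -> list[ParameterSpec]:
    """Parameter specs for the full study, optionally restricted to groups.

    Names must be unique; the packaged table guarantees this, and external
    tables read through :func:`specs_from_frame` are checked.
    """
    return specs_from_frame(load_parameter_table(), groups=groups)


def specs_from_frame(
    table: pd.DataFrame, groups: list[str] | None = None
) -> list[ParameterSpec]:
    """Build ParameterSpecs from a table with columns name, lower, upper, group."""
    if groups is not None:
        table = table[table["group"].isin(groups)]
    specs = [
        ParameterSpec(
            name=row["name"],
            lower=float(row["lower"]),
            upper=float(row["upper"]),
            group=row["group"],
            definition=str(row.get("definition", "")),
        )
        for _, row in table.iterrows()
    ]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("parameter names must be unique within a study")
    return specs


def load_sites() -> pd.DataFrame:
    """Site coordinates, seasonal weather summaries and management for the 8 sites."""
    with resources.as_file(_data_path("sites.csv")) as p:
        return pd.read_csv(p)


def load_soil_profile() -> pd.DataFrame:
    """Layered soil physical/chemical properties for the calibration site."""
    with resources.as_file(_data_path("soil_profile.csv")) as p:
        return pd.read_csv(p)


def load_observed_seasons() -> pd.DataFrame:
    """Observed sowing/anthesis/maturity dates, yield and biomass for five seasons."""
    with resources.as_file(_data_path("seasons.csv")) as p:
        return pd.read_csv(
            p, parse_dates=["sowing_date", "anthesis_date", "maturity_date"]
        )


def load_calibrated_coefficients() -> pd.DataFrame:
    """Default and calibrated values of the five most sensitive cultivar inputs."""
    with resources.as_file(_data_path("calibrated_coefficients.csv")) as p:
        return pd.read_csv(p)
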