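"""Study orchestration: per-site/per-year sensitivity runs, ranking,
temporal/spatial/pooled concordance, and evaluation statistics.

A study is declared in a YAML config: which site-years to analyse (one site
across years for the temporal axis, one year across sites for the spatial
axis), the EFAST settings, and the ranking index.  Every stage persists its
artifact as delimited text so any stage can be re-run from the previous
one, and the config plus seed are echoed into the output directory so the
whole report is re-derivable.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance, efast, evaluation, parameters, surrogate, weather

logger = logging.getLogger(__name__)

OUTPUT_NAMES = ["ADAP", "MDAP", "HWAM", "CWAM", "LAIX"]


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and, for missing artifacts,
    the subcommand that produces them."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    temporal_site: str = "Wuhan"
    temporal_years: list[int] = field(default_factory=lambda: [2016, 2017, 2018])
    spatial_year: int = 2018
    spatial_sites: list[str] = field(
        default_factory=lambda: ["Wuhan", "Luxi", "Hanzhong"]
    )
    M: int = 4
    Ns: int = 65
    Nr: int = 1
    seed: int = 1
    weather_seed: int = 7
    ranking_index: str = "total_order"
    parameter_groups: list[str] | None = None
    parameter_table: str | None = None
    outdir: str = "study_out"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise StageError("config", str(exc)) from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise StageError("config", f"unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @property
    def replicates(self) -> list[tuple[str, int]]:
        """All unique (site, year) replicates, temporal axis first."""
        reps = [(self.temporal_site, y) for y in self.temporal_years]
        for s in self.spatial_sites:
            if (s, self.spatial_year) not in reps:
                reps.append((s, self.spatial_year))
        return reps

    def specs(self) -> list[parameters.ParameterSpec]:
        if self.parameter_table:
            return parameters.specs_from_frame(
                pd.read_csv(self.parameter_table), groups=self.parameter_groups
            )
        return parameters.load_parameter_specs(groups=self.parameter_groups)


@dataclass
class StudyReport:
    sensitivity: dict[tuple[str, int], efast.SensitivityResult]
    rankings: dict[str, concordance.RankingSet]
    tdcc_table: pd.DataFrame
    outdir: Path


def _rep_label(site: str, year: int) -> str:
    return f"{site}_{year}"


def replicate_weather(
    config: StudyConfig, site_row: pd.Series, year: int
) -> tuple[pd.DataFrame, surrogate.Management]:
    """Deterministic synthetic season weather for one (site, year) replicate."""
    month, day = (int(x) for x in str(site_row["planting_date"]).split("-"))
    sowing = dt.date(year, month, day)
    seed = (config.weather_seed * 10007 + year * 101 + int(site_row.name)) % (2**31)
    n_days = 540
    frame = weather.synth_weather(
        latitude=float(site_row["latitude"]),
        start=sowing,
        n_days=n_days,
        mean_temp=float(site_row["mean_temp_C"]),
        season_rain=float(site_row["rain_mm"]) * n_days / 240.0,
        season_radiation=float(site_row["radiation_MJ_m2"]) * n_days / 240.0,
        seed=seed,
    )
    mgmt = surrogate.Management(
        sowing_date=sowing,
        population=float(site_row["population_per_m2"]),
        latitude=float(site_row["latitude"]),
    )
    return frame, mgmt


def _site_rows(config: StudyConfig) -> dict[str, pd.Series]:
    sites = parameters.load_sites()
    rows = {}
    for site, _ in config.replicates:
        match = sites[sites["site"] == site]
        if match.empty:
            raise StageError("config", f"unknown site {site!r}")
        rows[site] = match.iloc[0]
    return rows


def stage_sample(config: StudyConfig) -> efast.SampleMatrix:
    """Build the shared EFAST design and persist the realized sample matrix."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = config.specs()
    design = efast.build_design(
        specs, M=config.M, Ns=config.Ns, Nr=config.Nr, seed=config.seed
    )
    samples = efast.sample(design)
    pd.concat([samples.block_index, samples.values], axis=1).to_csv(
        outdir / "samples.csv", index=False
    )
    config.to_yaml(outdir / "config.yaml")
    return samples


def _load_samples(config: StudyConfig) -> pd.DataFrame:
    path = Path(config.outdir) / "samples.csv"
    if not path.exists():
        raise StageError("simulate", f"{path} missing; run the `sample` stage first")
    return pd.read_csv(path)


def stage_simulate(config: StudyConfig) -> dict[tuple[str, int], pd.DataFrame]:
    """Run the surrogate over the sample matrix for every replicate."""
    outdir = Path(config.outdir)
    samples = _load_samples(config)
    values = samples.drop(columns=["driving_factor", "curve", "position"])
    rows = _site_rows(config)
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for site, year in config.replicates:
        frame, mgmt = replicate_weather(config, rows[site], year)
        adapter = surrogate.make_efast_adapter(frame, management=mgmt)
        outputs = efast.evaluate_model_matrix(adapter, values)
        outputs.to_csv(outdir / f"outputs_{_rep_label(site, year)}.csv", index=False)
        out[(site, year)] = outputs
        logger.info("simulated replicate %s_%s (%d runs)", site, year, len(outputs))
    return out


def stage_indices(config: StudyConfig) -> dict[tuple[str, int], efast.SensitivityResult]:
    """Spectral variance decomposition per replicate."""
    outdir = Path(config.outdir)
    design = efast.build_design(
        config.specs(), M=config.M, Ns=config.Ns, Nr=config.Nr, seed=config.seed
    )
    results = {}
    for site, year in config.replicates:
        path = outdir / f"outputs_{_rep_label(site, year)}.csv"
        if not path.exists():
            raise StageError(
                "indices", f"{path} missing; run the `simulate` stage first"
            )
        outputs = pd.read_csv(path)
        res = efast.compute_indices(design, outputs)
        res.table.to_csv(
            outdir / f"indices_{_rep_label(site, year)}.csv", index=False
        )
        results[(site, year)] = res
    return results


def _load_indices(config: StudyConfig) -> dict[tuple[str, int], efast.SensitivityResult]:
    outdir = Path(config.outdir)
    results = {}
    for site, year in config.replicates:
        path = outdir / f"indices_{_rep_label(site, year)}.csv"
        if not path.exists():
            raise StageError("rank", f"{path} missing; run the `indices` stage first")
        table = pd.read_csv(path)
        results[(site, year)] = efast.SensitivityResult(
            table=table, variance={}, degenerate={}
        )
    return results


def stage_rank(config: StudyConfig) -> dict[str, concordance.RankingSet]:
    """Rank factors per replicate for every output variable."""
    outdir = Path(config.outdir)
    results = _load_indices(config)
    labels = [_rep_label(s, y) for s, y in config.replicates]
    rankings = {}
    for output in OUTPUT_NAMES:
        rs = concordance.rank_from_sensitivity(
            list(results.values()), output, index=config.ranking_index, labels=labels
        )
        rs.ranks.to_csv(outdir / f"ranks_{output}.csv")
        rankings[output] = rs
    return rankings


def _ranks_subset(
    rankings: dict[str, concordance.RankingSet], output: str, labels: list[str]
) -> concordance.RankingSet:
    frame = rankings[output].ranks[labels]
    return concordance.RankingSet(ranks=frame)


def stage_concord(
    config: StudyConfig, axes: tuple[str, ...] = ("temporal", "spatial", "total")
) -> pd.DataFrame:
    """TDCC per output along the temporal, spatial and pooled axes."""
    outdir = Path(config.outdir)
    rankings = {}
    for output in OUTPUT_NAMES:
        path = outdir / f"ranks_{output}.csv"
        if not path.exists():
            raise StageError("concord", f"{path} missing; run the `rank` stage first")
        rankings[output] = concordance.RankingSet(
            ranks=pd.read_csv(path, index_col=0)
        )
    temporal = [_rep_label(config.temporal_site, y) for y in config.temporal_years]
    spatial = [_rep_label(s, config.spatial_year) for s in config.spatial_sites]
    pooled = [_rep_label(s, y) for s, y in config.replicates]
    axis_labels = {"temporal": temporal, "spatial": spatial, "total": pooled}
    rows = []
    for output in OUTPUT_NAMES:
        for axis in axes:
            labels = axis_labels[axis]
            if len(labels) < 2:
                logger.info("axis %s has <2 replicates; skipped", axis)
                continue
            res = concordance.tdcc(_ranks_subset(rankings, output, labels))
            rows.append(
                {
                    "output": output,
                    "axis": axis,
                    "m_replicates": len(labels),
                    "TDCC": res.tdcc,
                    "T": res.T,
                    "p_value": res.p_value,
                }
            )
    columns = ["output", "axis", "m_replicates", "TDCC", "T", "p_value"]
    table = pd.DataFrame(rows, columns=columns)
    table.to_csv(outdir / "tdcc.csv", index=False)
    return table


def stage_evaluate(
    config: StudyConfig,
    coefficients: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Observed-vs-simulated statistics in the published table layout.

    Simulates the packaged five observed seasons with the surrogate (using
    the calibrated coefficient set unless overridden) and reports RMSE,
    nRMSE, ME, rME and d per attribute for calibration and evaluation years.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seasons = parameters.load_observed_seasons()
    params = surrogate.default_parameters()
    calib = parameters.load_calibrated_coefficients()
    for _, row in calib.iterrows():
        params[row["name"]] = float(row["calibrated"])
    if coefficients:
        params.update(coefficients)
    obs = {"anthesis": [], "maturity": [], "yield": [], "biomass": []}
    sim = {"anthesis": [], "maturity": [], "yield": [], "biomass": []}
    roles = []
    for _, row in seasons.iterrows():
        sowing = row["sowing_date"].date()
        frame, mgmt = surrogate.wuhan_weather(
            year=sowing.year, seed=config.weather_seed + sowing.year, sowing=sowing
        )
        out = surrogate.simulate_season(params, frame, management=mgmt)
        roles.append(row["role"])
        obs["anthesis"].append(
            evaluation.days_after_planting(sowing, row["anthesis_date"].date())
        )
        obs["maturity"].append(
            evaluation.days_after_planting(sowing, row["maturity_date"].date())
        )
        obs["yield"].append(float(row["yield_kg_ha"]))
        obs["biomass"].append(float(row["biomass_kg_ha"]))
        sim["anthesis"].append(out.ADAP)
        sim["maturity"].append(out.MDAP)
        sim["yield"].append(out.HWAM)
        sim["biomass"].append(out.CWAM)
    roles_arr = np.array(roles)
    rows = []
    for role in ("calibration", "evaluation"):
        mask = roles_arr == role
        for attr in ("anthesis", "maturity", "yield", "biomass"):
            stats = evaluation.fit_statistics(
                np.array(obs[attr])[mask], np.array(sim[attr])[mask]
            )
            rows.append(
                {
                    "period": role,
                    "attribute": attr,
                    "N": stats.N,
                    "RMSE": round(stats.RMSE, 2),
                    "nRMSE_pct": round(stats.nRMSE, 2),
                    "ME": round(stats.ME, 2),
                    "rME_pct": round(stats.rME, 2),
                    "d": round(stats.d, 2),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "evaluation_stats.csv", index=False)
    return table


def stage_report(config: StudyConfig, plots: bool = False) -> Path:
    """Render the concordance table and, optionally, SI profile figures."""
    outdir = Path(config.outdir)
    tdcc_path = outdir / "tdcc.csv"
    if not tdcc_path.exists():
        raise StageError("report", f"{tdcc_path} missing; run the `concord` stage first")
    table = pd.read_csv(tdcc_path)
    report_path = outdir / "report.txt"
    with open(report_path, "w") as fh:
        fh.write("Ranking-concordance summary (TDCC and p-values)\n")
        if table.empty:
            fh.write("(fewer than 2 replicates on every axis; no TDCC computed)\n")
        else:
            wide = table.pivot(
                index="output", columns="axis", values=["TDCC", "p_value"]
            )
            fh.write(wide.to_string(float_format=lambda v: f"{v:.3g}") + "\n")
    if plots:
        _plot_si_profiles(config, outdir)
    return report_path


def _plot_si_profiles(config: StudyConfig, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = _load_indices(config)
    fig, axes = plt.subplots(
        len(OUTPUT_NAMES), 1, figsize=(10, 3 * len(OUTPUT_NAMES)), sharex=True
    )
    for ax, output in zip(np.atleast_1d(axes), OUTPUT_NAMES):
        for (site, year), res in results.items():
            sub = res.table[res.table["output"] == output]
            ax.plot(
                sub["factor"], sub["STi"], marker="o", lw=0.8,
                label=_rep_label(site, year),
            )
        ax.set_ylabel(f"{output} STi")
        ax.tick_params(axis="x", rotation=90)
    np.atleast_1d(axes)[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "si_profiles.png", dpi=100)
    plt.close(fig)


def run_study(config: StudyConfig, plots: bool = False) -> StudyReport:
    """Execute the whole study: sample -> simulate -> indices -> rank -> TDCC."""
    stage_sample(config)
    stage_simulate(config)
    sensitivity = stage_indices(config)
    rankings = stage_rank(config)
    tdcc_table = stage_concord(config)
    stage_report(config, plots=plots)
    manifest = {
        "replicates": [list(r) for r in config.replicates],
        "n_runs_per_replicate": len(_load_samples(config)),
        "seed": config.seed,
        "weather_seed": config.weather_seed,
    }
    with open(Path(config.outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return StudyReport(
        sensitivity=sensitivity,
        rankings=rankings,
        tdcc_table=tdcc_table,
        outdir=Path(config.outdir),
    )
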