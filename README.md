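# canolagsa

Global sensitivity analysis and calibration support for rapeseed
(*Brassica napus*) crop-growth modelling in the Yangtze River basin setting:
which of the 35 genotype, ecotype and soil inputs of a daily crop model
actually drive its five season outputs (days to anthesis ADAP, days to
maturity MDAP, yield HWAM, above-ground biomass CWAM, maximum LAI LAIX),
how stable those parameter rankings are across years and sites, and how a
model calibrated on the influential subset scores on standard evaluation
statistics.

The package is written for crop modellers and agronomists who need a tested,
seedable implementation of this analysis chain. Its pieces:

- **EFAST** (`canolagsa.efast`) — extended Fourier Amplitude Sensitivity
  Test. Parameters are sampled along periodic search curves
  `x_j(s) = G(sin(ω_j s + φ_j))` with uniform margins; the output's Fourier
  spectrum at the driving frequency ω_max and its harmonics gives the
  first-order index `S_i = V_i / V(Y)`, and the spectral power below
  `ω_max/2` gives the total-order index `S_Ti = 1 − V_{−i} / V(Y)`.
- **Monte-Carlo Sobol oracle** (`canolagsa.sobol`) — Saltelli/Jansen
  pick-freeze estimators used as an independent cross-check in tests.
- **Ranking concordance** (`canolagsa.concordance`) — savage scores
  `S_i = Σ_{k=r_i}^n 1/k` and the top-down concordance coefficient
  `TDCC = [Σ_i (Σ_j S_ij)² − m²n] / [m²(n − Σ 1/i)]`, with significance from
  `T = m(n−1)·TDCC ~ χ²_{n−1}`.
- **Evaluation statistics** (`canolagsa.evaluation`) — RMSE, nRMSE, ME, rME
  and Willmott's d over paired observed/simulated seasons, with
  date-to-days-after-planting conversion and an nRMSE-sum calibration
  objective with grid search.
- **Weather tools** (`canolagsa.weather`) — FAO-56 solar geometry, the
  Angstrom radiation estimate `Rs = (a + b·n/N)·Ra` (a=0.2, b=0.5), a
  seeded synthetic-season generator hitting site summary targets, and
  CSV/DSSAT-dialect weather I/O.
- **Rapeseed surrogate** (`canolagsa.surrogate`) — a minimal, fully
  documented daily growth model exposing the same 35-parameter interface as
  the full crop model family, with designed causal structure (see
  `docs/methods.md`), so the pipeline runs without an external simulator.
- **Pipeline + CLI** (`canolagsa.pipeline`, console script `canolagsa`) —
  per-site/per-year study orchestration behind a YAML config, with every
  stage persisted as delimited text.

## Worked example

Estimate sensitivity indices for the Ishigami benchmark, whose variance
decomposition is known in closed form (S1=0.3139, S2=0.4424, S3=0,
ST3=0.2437):

```python
import math
from canolagsa import ParameterSpec, run_efast

specs = [ParameterSpec(f"x{i}", -math.pi, math.pi) for i in (1, 2, 3)]
def ishigami(p):
    return {"Y": math.sin(p["x1"]) + 7 * math.sin(p["x2"]) ** 2
                 + 0.1 * p["x3"] ** 4 * math.sin(p["x1"])}

result, samples, outputs = run_efast(ishigami, specs, Ns=1025, Nr=2, seed=3)
print(result.table.round(4))
```

```
  factor output      Si     STi
0     x1      Y  0.3110  0.5333
1     x2      Y  0.4420  0.4874
2     x3      Y  0.0260  0.2440
```

Each row is one input factor: `Si` is the fraction of output variance that
factor explains alone, `STi` the fraction it is involved in including
interactions — x2 is purely additive (Si ≈ STi ≈ 0.44), while x3 matters
only through its interaction with x1 (Si ≈ 0, STi ≈ 0.24).

The study itself runs from numbered drivers:

```bash
python analysis/01_synthesize_weather.py     # site weather from summary targets
python analysis/02_run_sensitivity_study.py  # per-site/per-year EFAST + TDCC
python analysis/03_calibration_recovery.py   # EM-FL grid-search recovery
python analysis/04_evaluation_statistics.py  # published-table audit + fit report
```

or through the CLI stage by stage
(`canolagsa sample|simulate|indices|rank|concord|evaluate|report -c study.yaml`).
Driver 02 prints, per output variable, the temporal/spatial/total TDCC with
p-values (all near 1 with p < 0.001 at the default settings: the influential
parameters are stable across years and sites) and the top total-order
drivers — EM-FL for phenology, TRIFL for LAI and biomass.

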