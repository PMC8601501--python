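# Methods

This note documents the models and estimators in `canolagsa`, the choices
made where the design was genuinely open, and what the synthetic study can
and cannot show about real crop-model behaviour.

## EFAST estimator

Each factor `X_j` is sampled along a periodic search curve

    x_j(s) = lower_j + span_j · (1/2 + arcsin(sin(ω_j s + φ_j)) / π),

with `s` at Ns points evenly spaced over (−π, π]. The arcsin transform makes
every factor's marginal exactly uniform on its range. One *block* of Ns runs
is generated per (factor, resample curve): the driven factor runs at the
driving frequency `ω_max = floor((Ns−1)/(2M))` and all others at
complementary frequencies at or below `floor(ω_max/(2M))`, so that no
complementary harmonic up to the interference order M (default 4) reaches
the driving band.

When the admissible complementary range 1..floor(ω_max/(2M)) has at least as
many slots as complementary factors, frequencies are spread as
`floor(linspace(1, floor(ω_max/(2M)), k−1))` rather than packed at 1, 2, …:
tightly commensurate complementary frequencies make the complementary
factors strongly correlated along the curve, which biases the along-curve
estimate of the total variance V(Y) (observable as a badly inflated S2 on
the Ishigami benchmark). With more factors than slots, frequencies cycle.

Per block, Fourier coefficients `A_p, B_p` are computed at integer
frequencies up to the Nyquist order (Ns−1)/2, and

    V_i  = 2 Σ_{p=1..M} (A_{p·ω_max}² + B_{p·ω_max}²),
    V(Y) = 2 Σ_{p≥1} (A_p² + B_p²),
    V_−i = 2 Σ_{p=1..floor(ω_max/2)} (A_p² + B_p²),
    S_i = V_i / V(Y),     S_Ti = 1 − V_−i / V(Y).

Indices are averaged over the Nr resample curves (fresh random phases each;
Nr defaults to 1, matching a single-pass study design). Spectral estimators
can stray slightly outside [0, 1]; estimates are clamped to [0, 1] and every
clamp is logged. An output whose spectral variance is below 1e-12 is flagged
degenerate and its indices reported as NaN with the flag set, rather than
dividing by ~0. Rows for which the model failed (exception or non-finite
output) poison their whole block — the spectrum needs a complete, evenly
spaced curve — and that block is dropped from the Nr average with a logged
warning.

Default design for the full 35-factor study: M=4, Ns=129, Nr=1, i.e. 4515
model runs — the nearest odd-curve-length spectral design to a 4520-run
study; the 5-run discrepancy is noted here deliberately.

Accuracy, measured in the test suite: on the Ishigami function at Ns=1025,
Nr=2 the estimates sit within ±0.05 of the closed-form indices; on additive
models Σ S_i lands in [0.95, 1.05]; agreement with the independent
Monte-Carlo Sobol oracle (Saltelli first-order, Jansen total-order,
pick-freeze with 10⁵ draws) is within ±0.03.

## Ranking concordance

Replicate analyses (years, sites) are compared on savage-scored rankings.
Ties in the sensitivity indices receive midranks, and tied factors get the
mean of the savage scores of the positions they span (recorded in the
ranking's tie log). Rankings use total-order indices by default — the
headline per-factor quantity — with first-order available by flag.

TDCC equals 1 exactly iff all replicates rank identically; significance uses
T = m(n−1)·TDCC against χ²_{n−1}. Two caveats documented here: the χ²
approximation is optimistic for very small n and m; and under independent
rankings the statistic is *not* centred at zero but at E[TDCC] = 1/m
(because E[T] = n−1 under the null). With m=7 replicates the null mean is
≈ 0.143; it vanishes only as m grows. Tests assert the 1/m law directly and
the near-zero mean at m=50.

## Evaluation statistics

For paired observed/simulated values: RMSE = √(Σ(P−O)²/N); ME = Σ(P−O)/N
with the sign convention simulated − observed; nRMSE and rME normalise by
the mean of the observed series, in percent; d is the Willmott index of
agreement. Phenology is always compared on days after planting (exact
calendar arithmetic, leap years honoured), never on calendar ordinals.
If all four values entering d's denominator coincide, d is defined as 1
when the numerator is also 0. The calibration objective is the equal-weight
sum of nRMSE over anthesis day, maturity day, yield and biomass; grid
search breaks loss ties toward the smaller parameter value.

Auditing the published statistics table against its own observed series
reproduces 7 of 8 rows' relative cells to two decimals from the printed
absolute errors; the calibration-year seed-yield row implies a normaliser
(~2571 kg/ha) inconsistent with its observed mean (2662 kg/ha) and is
flagged, not reproduced. The printed d values of 0.99 for N=2 phenology
rows are likewise inconsistent with the Willmott formula given the
reconstructed integer errors; d is computed but never asserted against the
published values.

## Weather construction

Extraterrestrial radiation Ra and daylength N use the FAO-56 solar-geometry
formulas (inverse relative Earth–Sun distance, solar declination, sunset
hour angle); an independent Spencer-series implementation serves as a
cross-check in tests (±0.5 MJ m⁻² d⁻¹). Sunshine hours convert to solar
radiation through the Angstrom relation with a=0.2, b=0.5.

The synthetic-season generator emulates only the site *summary* climate: a
sinusoidal annual temperature cycle (amplitude 11 °C, coldest mid-January)
plus Gaussian day-to-day noise shifted to the exact target mean; rain on
Bernoulli wet days (p=0.30) with gamma amounts rescaled to the exact season
total; radiation following the clear-sky seasonal shape rescaled to the
exact season total. The site tables label radiation per day but carry
season-total magnitudes (1708–2954 MJ m⁻²); the generator treats them as
season totals. What the generator does *not* emulate: autocorrelated
synoptic weather, heat waves and frost events, monsoon rain seasonality,
or covariance between cloud, rain and temperature. Passing tests therefore
show the pipeline's estimators behave correctly under controlled seasonal
forcing, not that the surrogate reproduces any site's actual weather
response.

## The rapeseed surrogate

The surrogate is deliberately not a reimplementation of a production crop
model: it is a minimal daily model with the same 35-parameter interface and
a *designed* causal structure, so that what the sensitivity pipeline should
find is known by construction. Phenology: thermal time above a 5 °C base
(scale 15 °C per thermal day), photothermal progress toward flowering
penalised by daylength deficit below CSDL (slope 0.015 h⁻¹; increased by
R1PPO after flowering) and by TMIN below OPTBI (slope 0.014 °C⁻¹ at the
nominal SLOBI, scaled by SLOBI/0.035); stage thresholds PL-EM, EM-V1,
JU-R0, EM-FL, FL-SH, FL-SD, SD-PM (shaped by PM09, LNGSH), then R7-R8
thermal days to harvest. Canopy: main-stem leaf appearance superlinear in
TRIFL (quadratic — branching), scaled by SIZLF, SLAVR and population, with
a specific-leaf-area-dependent LAI ceiling and post-expansion senescence.
Carbon: radiation-use efficiency (weakly modified by SLNF, SLOC, SBDM)
times intercepted PAR (extinction shaped by RWDTH, RHGHT) times thermal and
water stress, accumulating until physiological maturity; yield partitions
biomass gained during pod and seed fill with a coefficient shaped by PODUR,
SFDUR, SDPDV. Water: a layered tipping bucket on the packaged soil-profile
layer structure with sampled hydraulic scalars — capacity SDUL−SLLL,
saturation SSAT, drainage SLDR capped by SSKS, curve-number runoff SLRO,
stage-one evaporation limited by SLU1 and albedo SALB, root access
SRGF-weighted; the profile starts half depleted so a rainless season
develops stress. All 35 factors are live inputs; the nitrogen-side
parameters enter only as weak modifiers by design.

Two deliberate scale choices. First, the surrogate's photothermal-day unit
is compressed relative to the real crop (default parameters flower at
~50 days after sowing, not ~150): development rates carry a 0.05 daily
floor and moderate penalty slopes so that *every* point of the
35-dimensional parameter hypercube — including the joint slow-development
corners that EFAST search curves do visit — reaches harvest maturity inside
a 540-day weather window at the coldest study site. A realistically slow
phenology would overflow any fixed window at those corners. Consequently
the surrogate's absolute outputs are structural, not calibrated to observed
magnitudes, and the observed-vs-surrogate statistics report is layout
demonstration, not a fit claim. Second, the designed headline pattern —
EM-FL dominating anthesis, TRIFL dominating LAI and biomass, soil water
terms mattering more under low rain — is verified by the pipeline as a
joint smoke test of sampler, surrogate and estimator; it is a property of
this surrogate's construction, not a reproduction of any full crop model's
index magnitudes.

## Study orchestration and problem sizes

The pipeline runs one EFAST per (site, year) replicate with a shared design
(same seed, same sample matrix) so replicate rankings differ only through
weather; concordance is computed along three axes — temporal (one site
across years), spatial (one year across sites) and total (all unique
site-year replicates pooled; replicates appearing on both axes are pooled
once). Every stage persists delimited-text artifacts plus the config and
seeds, so a report is re-derivable from the config alone, and identical
seeds give bit-identical tables.

Problem sizes used by the shipped drivers and checks were chosen to keep a
full run in the minutes range on one CPU: the study driver uses Ns=65
(2275 runs per replicate, six replicates); the acceptance checks use the
full Ns=129 design (4515 runs) for one replicate, Ns=1025 for the analytic
benchmarks, 50 noise replicates for calibration recovery, and 200
simulations for the concordance null. Estimates at Ns=65 are noticeably
noisier than at Ns=129; ranking-based conclusions in the drivers are
robust to this, index magnitudes less so.

## Known limitations

- The χ²-based TDCC p-values are approximate for small n, m; no permutation
  p-values are provided.
- The EFAST implementation reports first- and total-order indices only; no
  pairwise interaction decomposition.
- The surrogate omits nitrogen dynamics, pest/disease, and management
  response beyond sowing date and population; its parameter→output map is
  designed, not fitted.
- The synthetic weather generator is a summary-statistics emulator; results
  under real weather series may differ, which is precisely why the weather
  I/O accepts external CSV/DSSAT-dialect files.
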