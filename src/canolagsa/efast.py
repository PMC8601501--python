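"""Extended Fourier Amplitude Sensitivity Test (EFAST).

Variance-based global sensitivity analysis: each input factor in turn drives
a periodic search curve through parameter space at a high frequency while the
remaining factors oscillate at low, non-interfering frequencies.  Reading the
model output's Fourier spectrum at the driving frequency and its harmonics
gives the variance contributed by that factor alone (the first-order index
S_i = V_i / V(Y)); the power left below the driving band estimates the
variance of everything *except* that factor, giving the total-order index
S_Ti = 1 - V_{-i} / V(Y), which includes all interactions involving it.

Sampling uses the arcsin search curve

    x_j(s) = lower_j + span_j * (1/2 + (1/pi) * arcsin(sin(w_j * s + phi_j)))

with s traversing (-pi, pi], which yields exactly uniform margins for each
factor.  The interference factor M (default 4) sets how many harmonics of the
driving frequency are attributed to the driven factor and how far the
complementary frequencies must stay below it to avoid aliasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSpec

logger = logging.getLogger(__name__)


class DegenerateOutputError(ValueError):
    """Raised when an output has (numerically) zero variance across the design."""


@dataclass(frozen=True)
class EFASTDesign:
    """A fully specified EFAST sampling plan.

    One block per (factor, curve): the block's factor runs at the driving
    frequency ``omega_max`` and every other factor at a complementary
    frequency.  Total model runs = k * Ns * Nr.
    """

    parameters: tuple[ParameterSpec, ...]
    interference_factor: int
    curve_length: int  # Ns, odd
    resample_curves: int  # Nr
    omega_max: int
    complementary_frequencies: dict[str, int]
    phases: np.ndarray = field(repr=False)  # (Nr, k, k) curve x driving x factor
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def n_runs(self) -> int:
        return self.k * self.curve_length * self.resample_curves

    def frequencies_for_block(self, driving_index: int) -> np.ndarray:
        """Per-factor angular frequencies when factor ``driving_index`` drives."""
        freqs = np.empty(self.k, dtype=int)
        comp = iter_complementary(self.omega_max, self.interference_factor, self.k - 1)
        j = 0
        for i in range(self.k):
            if i == driving_index:
                freqs[i] = self.omega_max
            else:
                freqs[i] = comp[j]
                j += 1
        return freqs


@dataclass
class SampleMatrix:
    """Realized parameter values plus the block bookkeeping needed to invert them."""

    values: pd.DataFrame  # columns = factor names, one row per model run
    block_index: pd.DataFrame  # columns: driving_factor, curve, position

    def __post_init__(self) -> None:
        if len(self.values) != len(self.block_index):
            raise ValueError("values and block_index must align row-for-row")


def iter_complementary(omega_max: int, M: int, count: int) -> np.ndarray:
    """Complementary frequencies for the non-driven factors.

    All complementary frequencies stay at or below floor(omega_max / (2M)) so
    no complementary harmonic up to order M reaches the driving band.  When
    that ceiling leaves room, the frequencies are spread evenly over
    1..floor(omega_max / (2M)) (minimising commensurability, which otherwise
    biases the along-curve total-variance estimate); when there are more
    complementary factors than admissible frequencies they cycle.
    """
    top = max(1, omega_max // (2 * M))
    if count <= 0:
        return np.array([], dtype=int)
    if top >= count:
        return np.floor(np.linspace(1, top, count)).astype(int)
    return np.array([1 + (i % top) for i in range(count)], dtype=int)


def build_design(
    parameters: list[ParameterSpec],
    M: int = 4,
    Ns: int = 129,
    Nr: int = 1,
    seed: int = 0,
) -> EFASTDesign:
    """Construct an EFAST design for ``parameters``.

    Parameters
    ----------
    M : interference factor (harmonics attributed to the driven factor).
    Ns : points per search curve; must be odd and large enough that the
        driving frequency ``floor((Ns-1)/(2M))`` is at least 1 and Nyquist-safe.
    Nr : number of independent resampling curves (fresh random phases each).
    seed : seeds the phase draws; identical seeds give identical designs.
    """
    parameters = list(parameters)
    k = len(parameters)
    if k < 2:
        raise ValueError("EFAST needs at least 2 factors (a complement set)")
    names = [p.name for p in parameters]
    if len(set(names)) != len(names):
        raise ValueError("parameter names must be unique")
    if Ns % 2 == 0:
        raise ValueError(f"curve length Ns must be odd, got {Ns}")
    if M < 1:
        raise ValueError("interference factor M must be >= 1")
    if Nr < 1:
        raise ValueError("resample count Nr must be >= 1")
    omega_max = (Ns - 1) // (2 * M)
    if omega_max < 1:
        raise ValueError(
            f"Ns={Ns} too small for M={M}: driving frequency would alias"
        )
    comp = iter_complementary(omega_max, M, k - 1)
    # phases: independent per curve, per driving block, per factor
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(Nr, k, k))
    # complementary frequency map (as used when each factor drives, the
    # remaining factors cycle in order)
    comp_map = {name: int(comp[min(i, len(comp) - 1)]) for i, name in enumerate(names)}
    return EFASTDesign(
        parameters=tuple(parameters),
        interference_factor=M,
        curve_length=Ns,
        resample_curves=Nr,
        omega_max=omega_max,
        complementary_frequencies=comp_map,
        phases=phases,
        seed=seed,
    )


def _s_grid(Ns: int) -> np.ndarray:
    """Ns points evenly spaced over (-pi, pi]."""
    return -np.pi + 2.0 * np.pi * np.arange(1, Ns + 1) / Ns


def search_curve(
    spec: ParameterSpec, omega: int, s: np.ndarray, phase: float
) -> np.ndarray:
    """Arcsin search curve mapping s to native units with uniform margins."""
    g = 0.5 + np.arcsin(np.sin(omega * s + phase)) / np.pi
    return spec.lower + spec.span * g


def sample(design: EFASTDesign) -> SampleMatrix:
    """Realize the design as a (k*Ns*Nr) x k matrix of parameter values."""
    s = _s_grid(design.curve_length)
    blocks = []
    index_rows = []
    for r in range(design.resample_curves):
        for i in range(design.k):
            freqs = design.frequencies_for_block(i)
            cols = {}
            for j, spec in enumerate(design.parameters):
                cols[spec.name] = search_curve(
                    spec, int(freqs[j]), s, float(design.phases[r, i, j])
                )
            blocks.append(pd.DataFrame(cols))
            index_rows.append(
                pd.DataFrame(
                    {
                        "driving_factor": design.names[i],
                        "curve": r,
                        "position": np.arange(design.curve_length),
                    }
                )
            )
    values = pd.concat(blocks, ignore_index=True)
    block_index = pd.concat(index_rows, ignore_index=True)
    return SampleMatrix(values=values, block_index=block_index)


@dataclass
class SensitivityResult:
    """First- and total-order sensitivity indices per (factor, output).

    ``table`` is tidy with columns: factor, output, Si, STi.
    ``variance`` maps output -> spectral estimate of V(Y) (mean over blocks).
    ``degenerate`` flags outputs whose variance was numerically zero.
    ``clamped`` counts index estimates clamped into [0, 1].
    """

    table: pd.DataFrame
    variance: dict[str, float]
    degenerate: dict[str, bool]
    clamped: int = 0

    def pivot(self, which: str = "STi") -> pd.DataFrame:
        return self.table.pivot(index="factor", columns="output", values=which)


def _spectrum(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fourier cosine/sine coefficients A_p, B_p for p = 1..(Ns-1)/2."""
    Ns = len(y)
    pmax = (Ns - 1) // 2
    p = np.arange(1, pmax + 1)
    # (pmax, Ns) outer products; Ns is modest so this stays cheap
    A = (np.cos(np.outer(p, s)) @ y) / Ns
    B = (np.sin(np.outer(p, s)) @ y) / Ns
    return A, B


def compute_indices(
    design: EFASTDesign,
    outputs: pd.DataFrame,
    variance_floor: float = 1e-12,
) -> SensitivityResult:
    """Estimate Si and STi for every (factor, output) pair from model outputs.

    ``outputs`` must have one row per design run, in the order produced by
    :func:`sample` (block-major: curve, then driving factor, then position).
    Rows containing NaN invalidate their whole block — the spectrum needs a
    complete, evenly spaced curve — and that block's estimates are dropped
    from the Nr average (all-NaN if every curve fails).

    Variance bookkeeping per block (Eqs below in the module docstring sense):
    V_i   = 2 * sum_{p=1..M} (A_{p*w}^2 + B_{p*w}^2) at the driving w,
    V(Y)  = 2 * sum_{p>=1}   (A_p^2 + B_p^2),
    V_-i  = 2 * sum_{p=1..floor(w/2)} (A_p^2 + B_p^2).
    """
    Ns = design.curve_length
    M = design.interference_factor
    w = design.omega_max
    s = _s_grid(Ns)
    out_names = list(outputs.columns)
    est: dict[str, dict[str, list]] = {
        o: {"Si": [[] for _ in range(design.k)], "STi": [[] for _ in range(design.k)]}
        for o in out_names
    }
    variances: dict[str, list[float]] = {o: [] for o in out_names}
    n_expected = design.n_runs
    if len(outputs) != n_expected:
        raise ValueError(
            f"outputs has {len(outputs)} rows; design expects {n_expected}"
        )
    clamped = 0
    harmonics = np.arange(1, M + 1) * w
    low_band = np.arange(1, w // 2 + 1)
    row = 0
    for r in range(design.resample_curves):
        for i in range(design.k):
            block = outputs.iloc[row : row + Ns]
            row += Ns
            for o in out_names:
                y = block[o].to_numpy(dtype=float)
                if not np.all(np.isfinite(y)):
                    logger.warning(
                        "block (factor=%s curve=%d output=%s) has failed runs; "
                        "block dropped from the average",
                        design.names[i], r, o,
                    )
                    continue
                A, B = _spectrum(y, s)
                power = A**2 + B**2
                V = 2.0 * power.sum()
                variances[o].append(V)
                if V < variance_floor:
                    continue  # degenerate; flagged after the loop
                Vi = 2.0 * power[harmonics - 1].sum()
                Vmi = 2.0 * power[low_band - 1].sum() if len(low_band) else 0.0
                Si = Vi / V
                STi = 1.0 - Vmi / V
                for name, val in (("Si", Si), ("STi", STi)):
                    if val < 0.0 or val > 1.0:
                        clamped += 1
                        logger.info(
                            "clamped %s=%.4f to [0,1] for factor=%s output=%s",
                            name, val, design.names[i], o,
                        )
                est[o]["Si"][i].append(min(max(Si, 0.0), 1.0))
                est[o]["STi"][i].append(min(max(STi, 0.0), 1.0))
    records = []
    variance: dict[str, float] = {}
    degenerate: dict[str, bool] = {}
    for o in out_names:
        vlist = variances[o]
        variance[o] = float(np.mean(vlist)) if vlist else float("nan")
        degenerate[o] = bool(vlist) and variance[o] < variance_floor
        for i, name in enumerate(design.names):
            si_list = est[o]["Si"][i]
            sti_list = est[o]["STi"][i]
            records.append(
                {
                    "factor": name,
                    "output": o,
                    "Si": float(np.mean(si_list)) if si_list else float("nan"),
                    "STi": float(np.mean(sti_list)) if sti_list else float("nan"),
                }
            )
    table = pd.DataFrame.from_records(records)
    return SensitivityResult(
        table=table, variance=variance, degenerate=degenerate, clamped=clamped
    )


def run_efast(
    model,
    parameters: list[ParameterSpec],
    M: int = 4,
    Ns: int = 129,
    Nr: int = 1,
    seed: int = 0,
    on_failure: str = "flag",
) -> tuple[SensitivityResult, SampleMatrix, pd.DataFrame]:
    """End-to-end EFAST: design, sample, evaluate the model, decompose.

    ``model`` maps a dict of parameter values (one full vector) to a dict of
    output values; exceptions or non-finite outputs flag the row.  With
    ``on_failure='raise'`` any failed run aborts; with ``'flag'`` (default)
    failed rows poison only their block (see :func:`compute_indices`).

    Returns the sensitivity result together with the realized sample and
    output matrices so callers can persist them for audit.
    """
    if on_failure not in {"flag", "raise"}:
        raise ValueError("on_failure must be 'flag' or 'raise'")
    design = build_design(parameters, M=M, Ns=Ns, Nr=Nr, seed=seed)
    samples = sample(design)
    rows = []
    for _, prow in samples.values.iterrows():
        try:
            out = model(prow.to_dict())
        except Exception:
            if on_failure == "raise":
                raise
            logger.warning("model failed on a run; row flagged")
            out = {}
        rows.append(out)
    outputs = pd.DataFrame(rows)
    if on_failure == "raise" and outputs.isna().any().any():
        raise RuntimeError("model returned non-finite outputs")
    result = compute_indices(design, outputs)
    return result, samples, outputs


def evaluate_model_matrix(model, values: pd.DataFrame) -> pd.DataFrame:
    """Evaluate a row-wise model adapter over a realized sample matrix."""
    rows = []
    for _, prow in values.iterrows():
        try:
            rows.append(model(prow.to_dict()))
        except Exception:
            logger.warning("model failed on a run; row flagged")
            rows.append({})
    return pd.DataFrame(rows)
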