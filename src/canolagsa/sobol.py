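"""Brute-force Monte-Carlo Sobol index estimator.

A pick-freeze estimator used as an independent cross-check of the spectral
EFAST estimator on cheap test functions.  First-order indices use the
Saltelli (2010) estimator and total-order indices the Jansen estimator:

    S_i  = mean( f(B) * (f(AB_i) - f(A)) ) / V
    S_Ti = mean( (f(A) - f(AB_i))^2 ) / (2 V)

where A and B are independent n x k sample matrices and AB_i is A with
column i taken from B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSpec


@dataclass
class SobolEstimate:
    names: list[str]
    Si: np.ndarray
    STi: np.ndarray
    n_draws: int
    warnings: list[str]


def sobol_mc_oracle(
    model,
    parameters: list[ParameterSpec],
    n_draws: int = 100_000,
    seed: int = 0,
) -> SobolEstimate:
    """Estimate first/total-order Sobol indices by pick-freeze Monte Carlo.

    ``model`` must accept an (n, k) array of parameter values in native units
    and return an (n,) array of outputs (vectorized, since the oracle needs
    n_draws * (k + 2) evaluations).
    """
    k = len(parameters)
    rng = np.random.default_rng(seed)
    msgs: list[str] = []
    if n_draws < 1000:
        msg = f"n_draws={n_draws} is small; Sobol MC estimates will be noisy"
        warnings.warn(msg, stacklevel=2)
        msgs.append(msg)
    lo = np.array([p.lower for p in parameters])
    span = np.array([p.span for p in parameters])
    A = lo + span * rng.random((n_draws, k))
    B = lo + span * rng.random((n_draws, k))
    fA = np.asarray(model(A), dtype=float)
    fB = np.asarray(model(B), dtype=float)
    V = np.var(np.concatenate([fA, fB]), ddof=1)
    Si = np.empty(k)
    STi = np.empty(k)
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = np.asarray(model(ABi), dtype=float)
        Si[i] = np.mean(fB * (fABi - fA)) / V
        STi[i] = np.mean((fA - fABi) ** 2) / (2.0 * V)
    return SobolEstimate(
        names=[p.name for p in parameters], Si=Si, STi=STi, n_draws=n_draws,
        warnings=msgs,
    )
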