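"""Ranking-stability statistics: savage scores and the top-down concordance
coefficient (TDCC).

When the same sensitivity analysis is repeated across years or sites, each
replicate yields a ranking of the factors.  The savage score transform

    S_i = sum_{k = r_i}^{n} 1/k

weights agreement at the top of the ranking most heavily; the TDCC over m
replicates of n factors,

    TDCC = [ sum_i (sum_j S_ij)^2 - m^2 n ] / [ m^2 (n - sum_{i=1}^n 1/i) ],

equals 1 exactly when all replicates rank identically and is near 0 for
independent rankings.  Significance uses T = m (n-1) TDCC against a
chi-squared distribution with n-1 degrees of freedom (an approximation that
is optimistic for very small n and m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .efast import SensitivityResult


@dataclass
class RankingSet:
    """Factor rankings across replicates; rank 1 = most sensitive.

    ``ranks`` is factors x replicates.  Columns may contain midranks (e.g.
    2.5 for a two-way tie at positions 2-3); ties must have been resolved
    before construction and any resolution is recorded in ``tie_events``.
    """

    ranks: pd.DataFrame
    tie_events: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.ranks)
        for col in self.ranks.columns:
            r = self.ranks[col].to_numpy(dtype=float)
            if not np.isclose(r.sum(), n * (n + 1) / 2):
                raise ValueError(
                    f"replicate {col!r}: ranks must be a (mid)ranking of 1..{n}"
                )

    @property
    def n_factors(self) -> int:
        return len(self.ranks)

    @property
    def n_replicates(self) -> int:
        return self.ranks.shape[1]


@dataclass
class TDCCResult:
    tdcc: float
    T: float
    df: int
    p_value: float
    savage_scores: pd.DataFrame


def savage_scores(ranks) -> np.ndarray:
    """Savage scores for one replicate's ranking (1 = top).

    Accepts midranks for ties: tied factors receive the mean of the savage
    scores of the positions they span.  Scores always sum to n.
    """
    r = np.asarray(ranks, dtype=float)
    n = len(r)
    if n == 0:
        raise ValueError("empty ranking")
    if not np.isclose(r.sum(), n * (n + 1) / 2) or r.min() < 1 or r.max() > n:
        raise ValueError("ranks must be a permutation of 1..n (midranks for ties)")
    # base scores for integer positions 1..n
    inv = 1.0 / np.arange(1, n + 1)
    base = np.cumsum(inv[::-1])[::-1]  # base[j] = sum_{k=j+1..n} 1/k at index j
    out = np.empty(n)
    for idx, ri in enumerate(r):
        if float(ri).is_integer():
            out[idx] = base[int(ri) - 1]
        else:
            # midrank m over a tied span of width t centred at m:
            # average the base scores of the tied integer positions
            ties = np.where(np.isclose(r, ri))[0]
            t = len(ties)
            start = int(round(ri - (t - 1) / 2.0))
            out[idx] = base[start - 1 : start - 1 + t].mean()
    return out


def tdcc(rankings: RankingSet) -> TDCCResult:
    """Top-down concordance coefficient across the replicates of a RankingSet."""
    n = rankings.n_factors
    m = rankings.n_replicates
    if n < 2:
        raise ValueError("TDCC needs at least 2 factors (denominator vanishes)")
    if m < 2:
        raise ValueError("TDCC needs at least 2 replicates")
    scores = np.column_stack(
        [savage_scores(rankings.ranks[c]) for c in rankings.ranks.columns]
    )
    row_sums = scores.sum(axis=1)
    denom = m**2 * (n - np.sum(1.0 / np.arange(1, n + 1)))
    value = (np.sum(row_sums**2) - m**2 * n) / denom
    T = m * (n - 1) * value
    df = n - 1
    p = float(stats.chi2.sf(T, df))
    return TDCCResult(
        tdcc=float(value),
        T=float(T),
        df=df,
        p_value=p,
        savage_scores=pd.DataFrame(
            scores, index=rankings.ranks.index, columns=rankings.ranks.columns
        ),
    )


def rank_from_sensitivity(
    results: list[SensitivityResult],
    output: str,
    index: str = "total_order",
    labels: list[str] | None = None,
) -> RankingSet:
    """Rank factors by descending sensitivity index, one replicate per result.

    ``index`` selects ``total_order`` (STi, the default headline quantity) or
    ``first_order`` (Si).  Ties receive midranks (average method), recorded in
    the RankingSet's tie log.
    """
    col = {"total_order": "STi", "first_order": "Si"}.get(index)
    if col is None:
        raise ValueError("index must be 'total_order' or 'first_order'")
    if not results:
        raise ValueError("no sensitivity results given")
    factor_sets = [tuple(sorted(r.table["factor"].unique())) for r in results]
    if len(set(factor_sets)) != 1:
        raise ValueError("all replicates must share the same factor set")
    labels = labels or [f"rep{j}" for j in range(len(results))]
    tie_events: list[str] = []
    cols = {}
    for lab, res in zip(labels, results):
        sub = res.table[res.table["output"] == output]
        if sub.empty:
            raise KeyError(f"output {output!r} not present in replicate {lab!r}")
        values = sub.set_index("factor")[col]
        ranks = values.rank(ascending=False, method="average")
        if values.duplicated().any():
            tie_events.append(f"{lab}: midranks assigned for tied {col}")
        cols[lab] = ranks
    frame = pd.DataFrame(cols).sort_index()
    return RankingSet(ranks=frame, tie_events=tie_events or None)
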