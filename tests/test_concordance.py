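"""Savage scores, top-down concordance and ranking construction."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canolagsa import RankingSet, rank_from_sensitivity, savage_scores, tdcc
from canolagsa.efast import SensitivityResult


def _savage_oracle(ranks):
    """Exact rational savage scores: S_i = sum_{k=r_i}^n 1/k."""
    n = len(ranks)
    return [sum(Fraction(1, k) for k in range(r, n + 1)) for r in ranks]


def _ranking_set(columns):
    frame = pd.DataFrame(
        {f"r{j}": col for j, col in enumerate(columns)},
        index=[f"f{i}" for i in range(len(columns[0]))],
    )
    return RankingSet(ranks=frame)


class TestSavageScores:
    def test_three_factor_example(self):
        assert savage_scores([1, 2, 3]) == pytest.approx([11 / 6, 5 / 6, 1 / 3])

    def test_single_factor(self):
        assert savage_scores([1]) == pytest.approx([1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.permutations(list(range(1, 9))))
    def test_scores_sum_to_n_and_match_rational_oracle(self, perm):
        scores = savage_scores(perm)
        oracle = _savage_oracle(perm)
        assert scores == pytest.approx([float(o) for o in oracle])
        assert float(sum(oracle)) == len(perm)  # telescoping identity, exact
        assert scores.sum() == pytest.approx(len(perm), abs=1e-12)

    def test_midranks_average_tied_positions(self):
        # positions 2 and 3 tied: both get (S(2)+S(3))/2
        scores = savage_scores([1, 2.5, 2.5, 4])
        plain = savage_scores([1, 2, 3, 4])
        assert scores[1] == scores[2] == pytest.approx((plain[1] + plain[2]) / 2)
        assert scores.sum() == pytest.approx(4.0)

    @pytest.mark.parametrize("bad", [[1, 1, 3], [0, 1, 2], [1, 2, 4]])
    def test_invalid_rankings_rejected(self, bad):
        with pytest.raises(ValueError):
            savage_scores(bad)


class TestTDCC:
    @pytest.mark.parametrize("n", range(2, 7))
    @pytest.mark.parametrize("m", range(2, 9))
    def test_identical_rankings_give_unity(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        perm = list(rng.permutation(n) + 1)
        res = tdcc(_ranking_set([perm] * m))
        assert res.tdcc == pytest.approx(1.0, abs=1e-10)

    def test_opposite_two_factor_rankings_give_zero(self):
        res = tdcc(_ranking_set([[1, 2], [2, 1]]))
        assert res.tdcc == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_significance_for_perfect_agreement(self):
        # n=5, m=8 identical: T = m(n-1) = 32, p = P(chi2_4 >= 32) ~ 1.9e-6
        res = tdcc(_ranking_set([[1, 2, 3, 4, 5]] * 8))
        assert res.T == pytest.approx(32.0, abs=1e-9)
        assert res.df == 4
        assert res.p_value == pytest.approx(1.913e-6, rel=1e-3)
        assert res.p_value < 0.001

    def test_unity_iff_identical_exhaustive_small(self):
        # n <= 4, m = 2: TDCC = 1 exactly when both rankings coincide
        for n in (2, 3, 4):
            first = list(range(1, n + 1))
            for perm in itertools.permutations(first):
                value = tdcc(_ranking_set([first, list(perm)])).tdcc
                if list(perm) == first:
                    assert value == pytest.approx(1.0, abs=1e-10)
                else:
                    assert value < 1.0 - 1e-10

    def test_invariant_to_replicate_relabeling_and_factor_order(self):
        rng = np.random.default_rng(7)
        cols = [list(rng.permutation(6) + 1) for _ in range(4)]
        base = tdcc(_ranking_set(cols))
        shuffled_reps = tdcc(_ranking_set([cols[2], cols[0], cols[3], cols[1]]))
        order = rng.permutation(6)
        reordered = tdcc(
            _ranking_set([list(np.array(c)[order]) for c in cols])
        )
        assert shuffled_reps.tdcc == pytest.approx(base.tdcc, abs=1e-12)
        assert reordered.tdcc == pytest.approx(base.tdcc, abs=1e-12)

    def test_p_value_monotone_decreasing_in_tdcc(self):
        from scipy import stats

        n, m = 10, 5
        ts = [m * (n - 1) * w for w in (0.2, 0.5, 0.8, 1.0)]
        ps = [stats.chi2.sf(t, n - 1) for t in ts]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_independent_rankings_center_on_one_over_m(self):
        # under the null T ~ chi2_{n-1}, so E[TDCC] = 1/m; with n=10, m=7
        # the mean over 200 simulations sits near 1/7, not 0
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            cols = [list(rng.permutation(10) + 1) for _ in range(7)]
            vals.append(tdcc(_ranking_set(cols)).tdcc)
        assert np.mean(vals) == pytest.approx(1 / 7, abs=0.05)

    def test_independent_rankings_mean_vanishes_with_many_replicates(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(200):
            cols = [list(rng.permutation(10) + 1) for _ in range(50)]
            vals.append(tdcc(_ranking_set(cols)).tdcc)
        assert abs(np.mean(vals)) <= 0.05

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError):
            tdcc(_ranking_set([[1], [1]]))


def _result_from_sti(sti: dict[str, float], output="ADAP"):
    table = pd.DataFrame(
        [
            {"factor": f, "output": output, "Si": v / 2, "STi": v}
            for f, v in sti.items()
        ]
    )
    return SensitivityResult(table=table, variance={}, degenerate={})


class TestRankFromSensitivity:
    def test_strictly_decreasing_indices_rank_in_order(self):
        res = _result_from_sti({"a": 0.9, "b": 0.5, "c": 0.1})
        rs = rank_from_sensitivity([res], "ADAP")
        assert list(rs.ranks["rep0"]) == [1, 2, 3]

    def test_identical_replicates_give_unit_tdcc(self):
        res = _result_from_sti({"a": 0.9, "b": 0.5, "c": 0.1, "d": 0.05})
        rs = rank_from_sensitivity([res, res], "ADAP")
        assert tdcc(rs).tdcc == pytest.approx(1.0, abs=1e-10)

    def test_first_order_flag_changes_ranking_basis(self):
        table = pd.DataFrame(
            [
                {"factor": "a", "output": "Y", "Si": 0.1, "STi": 0.9},
                {"factor": "b", "output": "Y", "Si": 0.8, "STi": 0.2},
            ]
        )
        res = SensitivityResult(table=table, variance={}, degenerate={})
        by_total = rank_from_sensitivity([res], "Y", index="total_order")
        by_first = rank_from_sensitivity([res], "Y", index="first_order")
        assert by_total.ranks.loc["a", "rep0"] == 1
        assert by_first.ranks.loc["a", "rep0"] == 2

    def test_ties_get_midranks_and_are_logged(self):
        res = _result_from_sti({"a": 0.5, "b": 0.5, "c": 0.1})
        rs = rank_from_sensitivity([res], "ADAP")
        assert rs.ranks.loc["a", "rep0"] == rs.ranks.loc["b", "rep0"] == 1.5
        assert rs.tie_events

    def test_mismatched_factor_sets_rejected(self):
        r1 = _result_from_sti({"a": 0.5, "b": 0.1})
        r2 = _result_from_sti({"a": 0.5, "c": 0.1})
        with pytest.raises(ValueError, match="factor set"):
            rank_from_sensitivity([r1, r2], "ADAP")
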