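"""EFAST design, sampling and spectral index estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canolagsa import (
    ParameterSpec,
    build_design,
    compute_indices,
    run_efast,
    sample,
    sobol_mc_oracle,
)
from canolagsa.efast import iter_complementary

from conftest import ISHIGAMI_SI, ISHIGAMI_STI


def _unit_specs(k):
    return [ParameterSpec(f"x{i}", 0.0, 1.0) for i in range(k)]


class TestBuildDesign:
    def test_driving_frequency_and_complement_set(self):
        design = build_design(_unit_specs(3), M=4, Ns=65)
        assert design.omega_max == 8
        for i in range(3):
            freqs = design.frequencies_for_block(i)
            assert freqs[i] == 8
            # floor(8 / (2*4)) = 1: every complementary factor at frequency 1
            assert set(freqs[np.arange(3) != i]) == {1}

    def test_total_runs_near_published_sample_count(self, study_specs):
        # 35 factors at Ns=129 gives 4515 runs, the nearest odd-curve design
        # to the 4520-run study
        design = build_design(study_specs, M=4, Ns=129, Nr=1)
        assert design.n_runs == 35 * 129 == 4515

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"Ns": 64},  # even curve length
            {"Ns": 7},  # omega_max would be 0
            {"Nr": 0},
            {"M": 0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        base = {"M": 4, "Ns": 65, "Nr": 1}
        base.update(kwargs)
        with pytest.raises(ValueError):
            build_design(_unit_specs(3), **base)

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_design(_unit_specs(1))

    def test_complementary_frequencies_respect_aliasing_ceiling(self):
        for count, M, wmax in [(34, 4, 16), (2, 4, 128), (10, 2, 64)]:
            comp = iter_complementary(wmax, M, count)
            assert len(comp) == count
            assert comp.min() >= 1
            assert comp.max() <= max(1, wmax // (2 * M))


class TestSample:
    def test_phase_zero_origin_is_midpoint(self):
        from canolagsa.efast import search_curve

        spec = ParameterSpec("x", 2.0, 10.0)
        val = search_curve(spec, omega=5, s=np.array([0.0]), phase=0.0)
        assert val[0] == pytest.approx(6.0)

    def test_values_respect_bounds_for_table_ranges(self, study_specs):
        design = build_design(study_specs, Ns=65, seed=3)
        sm = sample(design)
        for spec in study_specs:
            col = sm.values[spec.name]
            assert col.min() >= spec.lower - 1e-12
            assert col.max() <= spec.upper + 1e-12
        # the soil lower-limit factor spans its full published range per block
        slll = sm.values["SLLL"][sm.block_index["driving_factor"] == "SLLL"]
        assert slll.min() == pytest.approx(0.055, abs=2e-3)
        assert slll.max() == pytest.approx(0.123, abs=2e-3)

    def test_marginals_uniform_along_curve(self):
        design = build_design(_unit_specs(3), Ns=1025, seed=1)
        sm = sample(design)
        block = sm.values.iloc[:1025]
        for name in ("x0", "x1", "x2"):
            ks = stats.kstest(block[name], "uniform").statistic
            assert ks < 0.05

    def test_identical_seed_bit_identical_matrix(self, study_specs):
        a = sample(build_design(study_specs, Ns=65, seed=11)).values
        b = sample(build_design(study_specs, Ns=65, seed=11)).values
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_phases(self, study_specs):
        a = sample(build_design(study_specs, Ns=65, seed=11)).values
        b = sample(build_design(study_specs, Ns=65, seed=12)).values
        assert not a.equals(b)


class TestComputeIndices:
    def test_constant_output_flags_degenerate(self):
        design = build_design(_unit_specs(3), Ns=65)
        sm = sample(design)
        outputs = pd.DataFrame({"Y": np.full(len(sm.values), 3.14)})
        res = compute_indices(design, outputs)
        assert res.degenerate["Y"]
        assert res.table["Si"].isna().all()

    def test_additive_linear_model_matches_analytic_shares(self):
        # Y = X1 + 2 X2 with uniform inputs: Vi = ci^2/12 -> S1=0.2, S2=0.8
        specs = _unit_specs(2)
        res, _, _ = run_efast(
            lambda p: {"Y": p["x0"] + 2.0 * p["x1"]}, specs, Ns=1025, seed=0
        )
        t = res.table.set_index("factor")
        assert t.loc["x0", "Si"] == pytest.approx(0.2, abs=0.03)
        assert t.loc["x1", "Si"] == pytest.approx(0.8, abs=0.03)
        assert np.allclose(t["Si"], t["STi"], atol=0.02)
        assert 0.95 <= t["Si"].sum() <= 1.05

    def test_ishigami_matches_closed_form(self, ishigami_specs, ishigami_row_model):
        res, _, _ = run_efast(
            ishigami_row_model, ishigami_specs, Ns=1025, Nr=2, seed=3
        )
        t = res.table.set_index("factor")
        for name in ("x1", "x2", "x3"):
            assert t.loc[name, "Si"] == pytest.approx(ISHIGAMI_SI[name], abs=0.05)
        assert t.loc["x3", "STi"] == pytest.approx(ISHIGAMI_STI["x3"], abs=0.05)

    def test_total_order_dominates_first_order(self, ishigami_specs, ishigami_row_model):
        res, _, _ = run_efast(ishigami_row_model, ishigami_specs, Ns=513, seed=5)
        t = res.table
        assert (t["STi"] >= t["Si"] - 0.02).all()

    def test_affine_output_invariance(self, ishigami_specs, ishigami_row_model):
        design = build_design(ishigami_specs, Ns=513, seed=2)
        sm = sample(design)
        y = np.array(
            [
                p["x1"] + 0.5 * math.sin(3 * p["x2"]) * p["x3"]
                for p in sm.values.to_dict("records")
            ]
        )
        base = compute_indices(design, pd.DataFrame({"Y": y}))
        scaled = compute_indices(design, pd.DataFrame({"Y": -3.7 * y + 11.0}))
        pd.testing.assert_frame_equal(base.table, scaled.table, atol=1e-12)

    def test_failed_rows_invalidate_only_their_block(self):
        specs = _unit_specs(3)
        design = build_design(specs, Ns=65, seed=0)
        sm = sample(design)
        y = sm.values["x0"].to_numpy().copy()
        outputs = pd.DataFrame({"Y": y})
        outputs.iloc[5, 0] = np.nan  # one failure inside block 0
        res = compute_indices(design, outputs)
        t = res.table.set_index("factor")
        assert np.isnan(t.loc["x0", "Si"])  # its own block is gone
        assert np.isfinite(t.loc["x1", "Si"])
        assert np.isfinite(t.loc["x2", "Si"])

    def test_misaligned_outputs_rejected(self):
        design = build_design(_unit_specs(2), Ns=65)
        with pytest.raises(ValueError, match="rows"):
            compute_indices(design, pd.DataFrame({"Y": np.zeros(10)}))


class TestSobolOracleAgreement:
    def test_oracle_matches_ishigami_closed_form(
        self, ishigami_specs, ishigami_array_model
    ):
        est = sobol_mc_oracle(ishigami_array_model, ishigami_specs, 100_000, seed=1)
        for i, name in enumerate(("x1", "x2", "x3")):
            assert est.Si[i] == pytest.approx(ISHIGAMI_SI[name], abs=0.02)
            assert est.STi[i] == pytest.approx(ISHIGAMI_STI[name], abs=0.02)

    def test_single_factor_model_attribution(self):
        specs = _unit_specs(2)
        est = sobol_mc_oracle(lambda X: X[:, 0], specs, 50_000, seed=2)
        assert est.Si[0] == pytest.approx(1.0, abs=0.02)
        assert est.STi[1] == pytest.approx(0.0, abs=0.02)

    def test_efast_agrees_with_oracle_on_linear_k2(self):
        specs = [ParameterSpec("a", 0, 1), ParameterSpec("b", 0, 3)]
        res, _, _ = run_efast(
            lambda p: {"Y": 2 * p["a"] - p["b"]}, specs, Ns=1025, seed=4
        )
        est = sobol_mc_oracle(lambda X: 2 * X[:, 0] - X[:, 1], specs, 100_000, seed=4)
        t = res.table.set_index("factor")
        assert abs(t.loc["a", "Si"] - est.Si[0]) <= 0.03
        assert abs(t.loc["b", "Si"] - est.Si[1]) <= 0.03

    def test_efast_agrees_with_oracle_on_ishigami(
        self, ishigami_specs, ishigami_row_model, ishigami_array_model
    ):
        res, _, _ = run_efast(ishigami_row_model, ishigami_specs, Ns=1025, Nr=2, seed=6)
        est = sobol_mc_oracle(ishigami_array_model, ishigami_specs, 100_000, seed=6)
        t = res.table.set_index("factor")
        for i, name in enumerate(("x1", "x2", "x3")):
            assert abs(t.loc[name, "Si"] - est.Si[i]) <= 0.03

    def test_small_draw_count_warns(self, ishigami_specs, ishigami_array_model):
        with pytest.warns(UserWarning, match="noisy"):
            est = sobol_mc_oracle(ishigami_array_model, ishigami_specs, 500, seed=0)
        assert est.warnings
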