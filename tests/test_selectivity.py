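"""Background subtraction, reversal potentials, GHK permeability ratios."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from channelphys.constants import thermal_voltage_mV
from channelphys.selectivity import (
    IVCurve,
    estimate_erev,
    iv_from_ramp,
    pca_over_pna,
    pna_over_pk,
    selectivity_report,
    subtract_background,
)
from channelphys.solutions import activities
from channelphys.synthetic_data import PermeabilitySpec, simulate_ramp


def affine_iv(slope=0.1, erev=45.0, v=(-70, 60), n=131):
    grid = np.linspace(*v, n)
    return IVCurve(grid, slope * (grid - erev))


class TestSubtractBackground:
    def test_self_subtraction_is_zero(self):
        iv = affine_iv()
        out = subtract_background(iv, iv)
        np.testing.assert_allclose(out.current_uA, 0.0, atol=1e-12)

    def test_constant_offset_preserved(self):
        iv = affine_iv()
        shifted = IVCurve(iv.voltage_mV, iv.current_uA + 2.0)
        out = subtract_background(shifted, iv)
        np.testing.assert_allclose(out.current_uA, 2.0, atol=1e-12)

    def test_leak_removal_recovers_channel_current(self, solution_library):
        spec = PermeabilitySpec({"Na+": 1.0, "K+": 0.2})
        sol = solution_library["na_selectivity"]
        test = simulate_ramp(spec, sol, noise_sd_uA=0.0, leak_g_uS=2.0, seed=1)
        leak = simulate_ramp(spec, sol, noise_sd_uA=0.0, leak_g_uS=2.0, seed=1, channel_open=False)
        pure = simulate_ramp(spec, sol, noise_sd_uA=0.0, leak_g_uS=0.0, seed=1)
        corrected = subtract_background(iv_from_ramp(test), iv_from_ramp(leak))
        reference = iv_from_ramp(pure)
        np.testing.assert_allclose(corrected.current_uA, reference.current_uA, atol=1e-9)

    def test_small_overlap_rejected(self):
        a = IVCurve(np.linspace(-70, 60, 100), np.zeros(100))
        b = IVCurve(np.linspace(40, 60, 30), np.zeros(30))
        with pytest.raises(ValueError, match="overlap"):
            subtract_background(a, b)


class TestEstimateErev:
    def test_affine_curve_exact(self):
        est = estimate_erev(affine_iv(erev=45.0))
        assert est.erev_mV == pytest.approx(45.0, abs=1e-9)
        # the grid contains the root itself, so the bracket may touch zero
        assert est.i_low_uA <= 0 <= est.i_high_uA

    def test_two_point_bracket(self):
        iv = IVCurve(np.array([40.0, 50.0]), np.array([-5.0, 5.0]))
        assert estimate_erev(iv, smoothing_window=1).erev_mV == pytest.approx(45.0)

    def test_no_reversal_error(self):
        iv = IVCurve(np.linspace(-70, 60, 50), np.full(50, 3.0))
        with pytest.raises(ValueError, match="no reversal"):
            estimate_erev(iv)

    def test_degenerate_zero_curve(self):
        iv = IVCurve(np.linspace(-70, 60, 50), np.zeros(50))
        with pytest.raises(ValueError, match="degenerate"):
            estimate_erev(iv)

    def test_monotone_noiseless_error_below_half_grid_spacing(self, rng):
        """Against a brute-force root of the linear interpolant."""
        for _ in range(300):
            n = rng.integers(20, 200)
            v = np.linspace(-70, 60, n)
            increments = rng.uniform(0.01, 1.0, n - 1)
            i = np.cumsum(np.concatenate(([0.0], increments)))
            i -= rng.uniform(i[1], i[-2])  # force an interior crossing
            if i[0] == 0 or i[-1] == 0 or not (i[0] < 0 < i[-1]):
                continue
            est = estimate_erev(IVCurve(v, i))
            truth = brentq(lambda x: np.interp(x, v, i), v[0], v[-1])
            spacing = v[1] - v[0]
            assert abs(est.erev_mV - truth) <= spacing / 2


class TestMonovalentRatio:
    def test_symmetric_zero_shift_is_unity(self):
        assert pna_over_pk(140, 140, 10, 10).value == pytest.approx(1.0)

    def test_printed_reversal_potentials_give_4_9(self):
        # Erev(Na) = +46 mV, Erev(K) = +6 mV, symmetric 140 mM solutions, 20 degC
        res = pna_over_pk(140.0, 140.0, 46.0, 6.0, 293.15)
        assert round(res.value, 1) == 4.9
        assert res.delta_erev_mV == 40.0

    def test_reciprocal_shift(self):
        forward = pna_over_pk(140, 140, 40, 0).value
        backward = pna_over_pk(140, 140, 0, 40).value
        assert backward == pytest.approx(1.0 / forward, rel=1e-12)

    @given(
        a=st.floats(1, 300), b=st.floats(1, 300),
        e1=st.floats(-80, 80), e2=st.floats(-80, 80),
    )
    def test_swap_symmetry(self, a, b, e1, e2):
        x = pna_over_pk(a, b, e1, e2).value
        y = pna_over_pk(b, a, e2, e1).value
        assert x * y == pytest.approx(1.0, rel=1e-9)

    def test_strictly_increasing_in_delta_erev(self):
        values = [pna_over_pk(140, 140, d, 0.0).value for d in np.linspace(-60, 60, 25)]
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError):
            pna_over_pk(0.0, 140, 10, 0)


class TestDivalentRatio:
    def test_limiting_case_unity(self):
        # exp(E_Ca F/RT) -> 0 and dErev = 0 reduces the formula to a_Na/(4 a_Ca)
        res = pca_over_pna(4.0, 1.0, -2000.0, -2000.0)
        assert res.value == pytest.approx(1.0, rel=1e-9)

    def test_zero_potentials(self):
        assert pca_over_pna(1.0, 1.0, 0.0, 0.0).value == pytest.approx(0.5)

    def test_bath_like_activities_direct_evaluation(self):
        # independent evaluation of the formula at the activity-corrected
        # operating point (a_Na 105 mM, a_Ca 3.07 mM, E_Ca -30, E_Na +46 mV)
        vt = thermal_voltage_mV(293.15)
        expected = 105.0 * (1.0 + math.exp(-30.0 / vt)) / (4.0 * 3.07 * math.exp(76.0 / vt))
        res = pca_over_pna(105.0, 3.07, -30.0, 46.0, 293.15)
        assert res.value == pytest.approx(expected, rel=1e-12)
        assert res.value == pytest.approx(0.551, abs=1e-3)


class TestSelectivityReport:
    def _ramps(self, ratio, noise, seeds, solution_library):
        spec = PermeabilitySpec({"Na+": 1.0, "K+": 1.0 / ratio})
        ramps = []
        for k, seed in enumerate(seeds):
            oocyte = f"o{k + 1}"
            for cond, label in (("na", "na_selectivity"), ("k", "k_selectivity")):
                for open_ in (True, False):
                    ramps.append(
                        simulate_ramp(
                            spec, solution_library[label], noise_sd_uA=noise, seed=seed,
                            channel_open=open_, oocyte_id=oocyte,
                            condition=cond if open_ else f"{cond}_control",
                        )
                    )
        return ramps

    def test_recovers_known_ratio_across_oocytes(self, solution_library):
        ramps = self._ramps(4.9, noise=0.02, seeds=[11, 12, 13], solution_library=solution_library)
        results, summary = selectivity_report(ramps, solution_library)
        assert len(results) == 3
        row = summary.set_index("ratio").loc["P_Na/P_K"]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(4.9, rel=0.05)
        assert row["sd"] < 0.5  # identical cells: spread reflects noise only

    def test_missing_control_rejected(self, solution_library):
        ramps = self._ramps(4.9, 0.0, [1], solution_library)
        without_control = [r for r in ramps if r.condition != "na_control"]
        with pytest.raises(ValueError, match="missing control"):
            selectivity_report(without_control, solution_library)

    def test_identical_test_and_control_propagates_no_reversal(self, solution_library):
        spec = PermeabilitySpec({"Na+": 1.0, "K+": 1.0})
        sol = solution_library["na_selectivity"]
        ramps = [
            simulate_ramp(spec, sol, noise_sd_uA=0.0, seed=1, channel_open=False,
                          condition="na", oocyte_id="o1"),
            simulate_ramp(spec, sol, noise_sd_uA=0.0, seed=1, channel_open=False,
                          condition="na_control", oocyte_id="o1"),
        ]
        with pytest.raises(ValueError, match="degenerate|no reversal"):
            selectivity_report(ramps, solution_library)
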