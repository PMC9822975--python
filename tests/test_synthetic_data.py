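"""Simulator ground truth: determinism, analytic limits, phenomenology toggles."""

import math

import numpy as np
import pandas as pd
import pytest

from channelphys.constants import thermal_voltage_mV
from channelphys.recordings import ApplicationWindow, measure_response
from channelphys.selectivity import estimate_erev, iv_from_ramp, subtract_background
from channelphys.synthetic_data import (
    GatingModel,
    PermeabilitySpec,
    ProtocolSpec,
    ghk_reversal_mV,
    simulate_behavior,
    simulate_dose_response,
    simulate_ramp,
    simulate_step,
)
from channelphys.solutions import IonSpecies, SolutionComposition


def single_step_protocol(ph, seed=3, **kw):
    win = (ApplicationWindow(5.0, 13.0, "app", ph),)
    return ProtocolSpec(duration_s=18.0, windows=win, seed=seed, **kw)


@pytest.fixture(scope="module")
def na_140():
    return SolutionComposition(
        "na140", [IonSpecies("Na+", 1, 140.0), IonSpecies("Cl-", -1, 140.0)]
    )


class TestDeterminism:
    def test_step_bit_identical(self):
        a = simulate_step(GatingModel(), single_step_protocol(5.0, seed=9))
        b = simulate_step(GatingModel(), single_step_protocol(5.0, seed=9))
        np.testing.assert_array_equal(a.current_uA, b.current_uA)

    def test_ramp_and_tables_bit_identical(self, na_140):
        spec = PermeabilitySpec({"Na+": 1.0, "K+": 0.5})
        r1 = simulate_ramp(spec, na_140, seed=4)
        r2 = simulate_ramp(spec, na_140, seed=4)
        np.testing.assert_array_equal(r1.current_uA, r2.current_uA)
        d1 = simulate_dose_response([7.0, 6.5, 6.0, 5.5, 5.0], seed=4)
        d2 = simulate_dose_response([7.0, 6.5, 6.0, 5.5, 5.0], seed=4)
        pd.testing.assert_frame_equal(d1.data, d2.data)
        c1, t1 = simulate_behavior({"wt": 20.0}, capture_median_s={"wt": 60.0}, seed=4)
        c2, t2 = simulate_behavior({"wt": 20.0}, capture_median_s={"wt": 60.0}, seed=4)
        pd.testing.assert_frame_equal(c1.data, c2.data)
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestStepSimulator:
    def test_closed_channel_at_neutral_ph(self):
        protocol = single_step_protocol(7.4)
        rec = simulate_step(GatingModel(), protocol)
        m = measure_response(rec, "app")
        assert abs(m.sustained_uA - m.baseline_uA) < 3 * protocol.noise_sd_uA

    def test_saturating_amplitude_matches_driving_force(self):
        # no desensitization in play: step amplitude above the resting level
        # is g_max * (P_open(sat) - P_open(rest)) * |Vh - Erev|
        model = GatingModel(ph50=6.5, desens_onset_ph=3.0, d_floor_ph=2.0)
        protocol = single_step_protocol(4.5, noise_sd_uA=0.0)
        rec = simulate_step(model, protocol)
        m = measure_response(rec, "app")
        d_open = model.hill_open(10.0 ** -4.5) - model.hill_open(10.0 ** -7.4)
        expected = model.g_max_uS * d_open * abs(-70.0 - model.erev_mV) * 1e-3
        assert m.sustained_amplitude_uA == pytest.approx(expected, rel=0.01)

    def test_biphasic_ratio_approaches_desensitization_floor(self):
        # near-instant solution exchange, acquisition filter off: the
        # transient/sustained ratio approaches 1/d_floor
        model = GatingModel(d_floor=0.3, tau_d_s=1.0)
        protocol = single_step_protocol(
            4.0, noise_sd_uA=0.0, exchange_tau_s=0.01, lowpass_hz=None
        )
        m = measure_response(simulate_step(model, protocol), "app")
        assert m.biphasic
        assert m.transient_sustained_ratio == pytest.approx(1.0 / 0.3, rel=0.10)

    def test_overlapping_windows_rejected(self):
        wins = (
            ApplicationWindow(1.0, 5.0, "a", 6.0),
            ApplicationWindow(4.0, 8.0, "b", 5.0),
        )
        with pytest.raises(ValueError, match="overlap"):
            ProtocolSpec(duration_s=10.0, windows=wins, seed=0)

    def test_egta_removes_cacc_transient(self):
        base = dict(ph=6.0, seed=3, noise_sd_uA=0.02)
        plain = simulate_step(GatingModel(), single_step_protocol(**base))
        contaminated = simulate_step(GatingModel(), single_step_protocol(**base, cacc=True))
        chelated = simulate_step(
            GatingModel(), single_step_protocol(**base, cacc=True, egta=True)
        )
        transient = np.abs(contaminated.current_uA - plain.current_uA).max()
        assert transient > 0.2  # the contamination is present...
        np.testing.assert_array_equal(chelated.current_uA, plain.current_uA)  # ...and EGTA removes it


class TestRampSimulator:
    def test_symmetric_biionic_reverses_at_zero(self, na_140):
        spec = PermeabilitySpec({"Na+": 1.0, "K+": 1.0}, internal_mM={"Na+": 0.0, "K+": 140.0})
        ramp = simulate_ramp(spec, na_140, noise_sd_uA=0.0, leak_g_uS=0.0,
                             use_activities=False, lowpass_hz=None)
        est = estimate_erev(iv_from_ramp(ramp))
        assert est.erev_mV == pytest.approx(0.0, abs=0.05)

    def test_noiseless_erev_matches_ghk_closed_form(self, na_140):
        ratio = 4.9
        spec = PermeabilitySpec(
            {"Na+": 1.0, "K+": 1.0 / ratio}, internal_mM={"Na+": 0.0, "K+": 140.0}
        )
        ramp = simulate_ramp(spec, na_140, noise_sd_uA=0.0, leak_g_uS=0.0,
                             use_activities=False, lowpass_hz=None)
        est = estimate_erev(iv_from_ramp(ramp))
        closed_form = thermal_voltage_mV(spec.temperature_K) * math.log(ratio)
        assert est.erev_mV == pytest.approx(closed_form, abs=0.05)
        assert ghk_reversal_mV(spec, {"Na+": 140.0}) == pytest.approx(closed_form, abs=1e-6)

    def test_leak_only_control_self_subtracts(self, na_140):
        spec = PermeabilitySpec({"Na+": 1.0})
        ctrl = simulate_ramp(spec, na_140, noise_sd_uA=0.0, seed=1, channel_open=False)
        out = subtract_background(iv_from_ramp(ctrl), iv_from_ramp(ctrl))
        np.testing.assert_allclose(out.current_uA, 0.0, atol=1e-12)

    def test_zero_permeability_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            PermeabilitySpec({"Na+": 0.0})


class TestDoseAndBehaviorTables:
    def test_zero_noise_lies_on_hill_curve(self):
        table = simulate_dose_response(
            [1e-7, 1e-6, 1e-5, 1e-4], "molar", "activation",
            half_max_M=1e-5, noise_cv=0.0, n_replicates=1, amplitude_uA=1.0, seed=0,
        )
        conc = table.concentrations()
        expected = conc / (conc + 1e-5)
        np.testing.assert_allclose(table.data["response_uA"].to_numpy(), expected, rtol=1e-12)

    def test_zero_mean_group_all_zero_counts(self):
        counts, _ = simulate_behavior({"dead": 0.0, "wt": 25.0}, seed=2)
        dead = counts.data[counts.data.treatment == "dead"]
        assert (dead["count"] == 0).all()

    def test_capture_times_ordered_and_skewed(self):
        _, times = simulate_behavior(
            {}, capture_median_s={"ctrl": 60.0}, n_per_group=30, seed=8
        )
        wide = times.data.pivot(index="animal_id", columns="event", values="time_s")
        assert (wide["first"] <= wide["second"]).all()
        assert (wide["second"] <= wide["third"]).all()
        t = times.data["time_s"]
        assert t.mean() > t.median()  # right skew
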