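"""Synthetic TEVC recordings and assay tables with known ground truth.

Every input the analysis modules consume can be generated here, with the
statistical and biophysical structure the analysis assumes, so the whole
pipeline is testable without access to raw oocyte recordings:

* **Step currents** -- proton-gated conductance with Hill activation,
  first-order solution exchange at the membrane, and desensitization to a
  pH-dependent floor, which makes responses biphasic at strongly acidic pH
  (a fast transient relaxing to a sustained plateau).  An optional
  Ca2+-activated chloride (CaCC) contamination transient can be added and
  is suppressed by the EGTA toggle, mimicking chelator-injected oocytes.
  Gaussian recording noise is low-pass filtered (4th-order Butterworth,
  20 Hz corner) to match bench acquisition (1 kHz sampling, 20 Hz filter).
* **Ramp currents** -- per-ion Goldman-Hodgkin-Katz constant-field fluxes
  (valence-2 term for Ca2+) summed over a -70 to +60 mV / 6 s command, plus
  a linear leak; the leak-only companion ramp plays the pH 7.4 background
  control.  The noiseless reversal potential obeys the GHK voltage
  equation, so specified permeability ratios are recovered exactly by the
  selectivity pipeline.
* **Dose-response tables** -- replicate amplitudes on a Hill curve with
  per-oocyte expression scaling and multiplicative noise.
* **Behavior tables** -- Poisson discharge counts scaled by imaged area and
  right-skewed (lognormal) capture times with ordered first/second/third
  events (order statistics of three draws).

The desensitization and CaCC forms are deliberate stand-ins chosen for
testability; they reproduce the phenomenology the analysis must classify,
not measured channel kinetics.  All randomness flows through one seeded
generator per call; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .behavior_stats import CaptureTimeTable, DischargeCountTable
from .constants import DEFAULT_TEMPERATURE_K, thermal_voltage_mV
from .dose_response import DoseResponseTable, ph_to_concentration
from .recordings import ApplicationWindow, RampRecording, StepRecording
from .solutions import SolutionComposition, activities

__all__ = [
    "GatingModel",
    "PermeabilitySpec",
    "ProtocolSpec",
    "simulate_step",
    "simulate_ramp",
    "simulate_dose_response",
    "simulate_behavior",
    "ghk_reversal_mV",
]

ION_VALENCE = {"Na+": 1, "K+": 1, "Ca2+": 2, "Cl-": -1, "NMDG+": 1, "Mg2+": 2}

#: oocyte-typical internal milieu (mM); placeholders, configurable
DEFAULT_INTERNAL_MM = {"Na+": 10.0, "K+": 110.0, "Ca2+": 1e-4}


@dataclass(frozen=True)
class GatingModel:
    """Proton-gated conductance with desensitization to a pH-dependent floor."""

    g_max_uS: float = 50.0
    ph50: float = 5.8
    hill_n: float = 1.0
    desens_onset_ph: float = 5.5
    d_floor: float = 0.3  # steady-state open fraction retained at d_floor_ph
    d_floor_ph: float = 4.0
    tau_d_s: float = 1.0
    erev_mV: float = 40.0  # channel reversal for step-mode driving force

    def __post_init__(self) -> None:
        if self.tau_d_s <= 0:
            raise ValueError("desensitization time constant must be > 0")
        if not 0.0 <= self.d_floor <= 1.0:
            raise ValueError("d_floor must lie in [0, 1]")
        if self.d_floor_ph >= self.desens_onset_ph:
            raise ValueError("d_floor_ph must be more acidic than desens_onset_ph")

    def hill_open(self, h_activity_M: np.ndarray | float) -> np.ndarray | float:
        """Steady-state activation: Hill function of proton activity."""
        ec50 = 10.0 ** (-self.ph50)
        hn = np.power(h_activity_M, self.hill_n)
        return hn / (hn + ec50**self.hill_n)

    def d_inf(self, ph: np.ndarray | float) -> np.ndarray | float:
        """Steady-state desensitized fraction retained: 1 above onset,
        declining linearly to ``d_floor`` at ``d_floor_ph``."""
        ph = np.asarray(ph, dtype=float)
        frac = (self.desens_onset_ph - ph) / (self.desens_onset_ph - self.d_floor_ph)
        d = 1.0 - np.clip(frac, 0.0, 1.0) * (1.0 - self.d_floor)
        return d if d.ndim else float(d)


@dataclass(frozen=True)
class PermeabilitySpec:
    """Relative permeabilities (P_X / P_Na) and internal milieu for GHK ramps."""

    relative_permeability: Mapping[str, float]
    internal_mM: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INTERNAL_MM))
    temperature_K: float = DEFAULT_TEMPERATURE_K
    scale_uA: float = 0.02  # overall flux scale: microampere per mM of driving term

    def __post_init__(self) -> None:
        if not self.relative_permeability:
            raise ValueError("at least one permeant ion required")
        for ion, p in self.relative_permeability.items():
            if p <= 0:
                raise ValueError(f"relative permeability for {ion} must be > 0")
            if ion not in ION_VALENCE:
                raise ValueError(f"unknown ion {ion!r}")


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition and solution-exchange protocol for step simulations."""

    duration_s: float
    windows: tuple[ApplicationWindow, ...]
    holding_mV: float = -70.0
    sampling_rate_hz: float = 1000.0
    lowpass_hz: float | None = 20.0
    baseline_ph: float = 7.4
    exchange_tau_s: float = 0.5
    noise_sd_uA: float = 0.02
    seed: int = 0
    cacc: bool = False  # Ca2+-activated Cl- contamination transient
    egta: bool = False  # chelator injected: suppresses the CaCC transient
    cacc_amplitude_uA: float = 2.0
    cacc_tau_s: float = 0.3

    def __post_init__(self) -> None:
        wins = sorted(self.windows, key=lambda w: w.start_s)
        for a, b in zip(wins, wins[1:]):
            if b.start_s < a.end_s:
                raise ValueError(f"application windows {a.label!r} and {b.label!r} overlap")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def _lowpass(current: np.ndarray, fs: float, corner_hz: float | None) -> np.ndarray:
    if corner_hz is None or corner_hz >= fs / 2:
        return current
    sos = signal.butter(4, corner_hz, btype="low", fs=fs, output="sos")
    # causal filtering, as done at acquisition time; pad start with the
    # initial value so the filter starts settled at the baseline
    zi = signal.sosfilt_zi(sos) * current[0]
    out, _ = signal.sosfilt(sos, current, zi=zi)
    return out


def simulate_step(model: GatingModel, protocol: ProtocolSpec) -> StepRecording:
    """Simulate a holding-potential recording under a pH application schedule.

    The proton activity at the membrane relaxes exponentially (solution
    exchange) to each window's applied pH; the open fraction is
    Hill([H+]) x d(t), with d(t) relaxing to d_inf(pH) with tau_d.  The
    ionic current is g_max * open * (V_hold - E_rev), plus the optional
    CaCC transient and filtered Gaussian noise.
    """
    fs = protocol.sampling_rate_hz
    n = int(round(protocol.duration_s * fs)) + 1
    t = np.arange(n) / fs
    dt = 1.0 / fs

    target_ph = np.full(n, protocol.baseline_ph)
    for w in protocol.windows:
        if w.stimulus_kind != "pH":
            raise ValueError(f"step simulation expects pH windows, got {w.stimulus_kind!r}")
        target_ph[(t >= w.start_s) & (t < w.end_s)] = w.stimulus

    # membrane [H+]: first-order exchange toward the bath target
    h_target = 10.0 ** (-target_ph)
    alpha_ex = math.exp(-dt / protocol.exchange_tau_s)
    h = np.empty(n)
    h[0] = h_target[0]
    for k in range(1, n):
        h[k] = h_target[k] + (h[k - 1] - h_target[k]) * alpha_ex

    local_ph = -np.log10(h)
    d_target = model.d_inf(local_ph)
    alpha_d = math.exp(-dt / model.tau_d_s)
    d = np.empty(n)
    d[0] = d_target[0]
    for k in range(1, n):
        d[k] = d_target[k] + (d[k - 1] - d_target[k]) * alpha_d

    open_frac = np.asarray(model.hill_open(h)) * d
    current = model.g_max_uS * open_frac * (protocol.holding_mV - model.erev_mV) * 1e-3

    if protocol.cacc and not protocol.egta:
        # contamination transient at each application onset, scaled by how far
        # the channel opens; suppressed entirely by injected EGTA
        for w in protocol.windows:
            after = t >= w.start_s
            rel = t[after] - w.start_s
            gate = float(np.max(open_frac[(t >= w.start_s) & (t < w.end_s)], initial=0.0))
            shape = (1.0 - np.exp(-rel / (protocol.cacc_tau_s / 6.0))) * np.exp(
                -rel / protocol.cacc_tau_s
            )
            current[after] -= protocol.cacc_amplitude_uA * gate * shape

    rng = np.random.default_rng(protocol.seed)
    current = current + rng.normal(0.0, protocol.noise_sd_uA, size=n)
    current = _lowpass(current, fs, protocol.lowpass_hz)

    return StepRecording(
        time_s=t,
        current_uA=current,
        holding_mV=protocol.holding_mV,
        sampling_rate_hz=fs,
        windows=protocol.windows,
        construct="synthetic",
    )


# ---------------------------------------------------------------------------
# GHK voltage ramps


def _ghk_flux_term(v_mV: np.ndarray, z: int, c_in: float, c_out: float, vt_mV: float) -> np.ndarray:
    """Constant-field flux shape: z^2 * w * (c_in - c_out e^{-zw}) / (1 - e^{-zw}),
    with w = V / (RT/F); finite limit z*(c_in - c_out) at V = 0."""
    w = np.asarray(v_mV, dtype=float) / vt_mV
    zw = z * w
    small = np.abs(zw) < 1e-8
    zw_safe = np.where(small, 1.0, zw)
    frac = np.where(
        small,
        (c_in - c_out) / z + 0.5 * (c_in + c_out) * w,  # first-order expansion
        w * (c_in - c_out * np.exp(-zw_safe)) / (1.0 - np.exp(-zw_safe)),
    )
    return z**2 * frac


def ghk_reversal_mV(
    spec: PermeabilitySpec,
    outer_activity_mM: Mapping[str, float],
) -> float:
    """Zero of the summed noiseless GHK flux (numeric root; closed form for
    pure monovalent mixtures coincides with the GHK voltage equation)."""
    vt = thermal_voltage_mV(spec.temperature_K)

    def total(v: float) -> float:
        s = 0.0
        for ion, p in spec.relative_permeability.items():
            z = ION_VALENCE[ion]
            c_in = spec.internal_mM.get(ion, 0.0)
            c_out = outer_activity_mM.get(ion, 0.0)
            s += p * float(_ghk_flux_term(np.array([v]), z, c_in, c_out, vt)[0])
        return s

    from scipy.optimize import brentq

    lo, hi = -200.0, 200.0
    if total(lo) * total(hi) > 0:
        raise ValueError("no GHK reversal in [-200, 200] mV for this ion mix")
    return float(brentq(total, lo, hi, xtol=1e-10))


def simulate_ramp(
    spec: PermeabilitySpec,
    outer: SolutionComposition,
    ramp_spec: tuple[float, float, float] = (-70.0, 60.0, 6.0),
    sampling_rate_hz: float = 1000.0,
    leak_g_uS: float = 1.0,
    leak_erev_mV: float = -20.0,
    noise_sd_uA: float = 0.02,
    seed: int = 0,
    channel_open: bool = True,
    use_activities: bool = True,
    lowpass_hz: float | None = 20.0,
    condition: str = "",
    oocyte_id: str = "",
) -> RampRecording:
    """Voltage-ramp current: summed per-ion GHK fluxes + linear leak + noise,
    low-pass filtered as at acquisition (20 Hz corner by default).

    ``channel_open=False`` produces the leak-only companion control (the
    pH 7.4 background ramp); its noise stream is independent of the test
    ramp's even at the same seed.  The acquisition filter is linear, so
    background subtraction still cancels the leak exactly, and its group
    delay shifts both bi-ionic reversal potentials equally, leaving Erev
    differences intact.
    """
    v0, v1, dur = ramp_spec
    n = int(round(dur * sampling_rate_hz)) + 1
    t = np.arange(n) / sampling_rate_hz
    v = v0 + (v1 - v0) * t / dur

    vt = thermal_voltage_mV(spec.temperature_K)
    outer_conc: dict[str, float]
    if use_activities:
        outer_conc = dict(activities(outer).activity_mM)
    else:
        outer_conc = {s.name: s.mM for s in outer.species}

    current = leak_g_uS * (v - leak_erev_mV) * 1e-3
    if channel_open:
        for ion, p in spec.relative_permeability.items():
            z = ION_VALENCE[ion]
            c_in = spec.internal_mM.get(ion, 0.0)
            c_out = outer_conc.get(ion, 0.0)
            current = current + spec.scale_uA * p * _ghk_flux_term(v, z, c_in, c_out, vt)

    role = 0 if channel_open else 1
    rng = np.random.default_rng([seed, role])
    if noise_sd_uA > 0:
        current = current + rng.normal(0.0, noise_sd_uA, size=n)
    current = _lowpass(current, sampling_rate_hz, lowpass_hz)

    return RampRecording(
        time_s=t,
        voltage_mV=v,
        current_uA=current,
        ramp_spec=ramp_spec,
        condition=condition or ("test" if channel_open else "control"),
        oocyte_id=oocyte_id,
        solution_label=outer.label,
    )


# ---------------------------------------------------------------------------
# Dose-response tables


def simulate_dose_response(
    stimuli: Sequence[float],
    stimulus_kind: Literal["pH", "molar"] = "pH",
    direction: Literal["activation", "inhibition"] = "activation",
    half_max_M: float = 10.0 ** -5.8,
    hill_n: float = 1.0,
    f_res: float = 0.0,
    n_replicates: int = 9,
    noise_cv: float = 0.05,
    amplitude_uA: float = 5.0,
    seed: int = 0,
) -> DoseResponseTable:
    """Replicate response amplitudes on a Hill curve with multiplicative noise.

    Each replicate (oocyte) gets a lognormal expression scale around
    ``amplitude_uA``; every point is perturbed by ``1 + noise_cv * N(0,1)``.
    """
    rng = np.random.default_rng(seed)
    conc = np.array(
        [ph_to_concentration(s) if stimulus_kind == "pH" else float(s) for s in stimuli]
    )
    if direction == "activation":
        curve = conc**hill_n / (conc**hill_n + half_max_M**hill_n)
    else:
        curve = f_res + (1.0 - f_res) / (1.0 + (conc / half_max_M) ** hill_n)

    rows = []
    for r in range(n_replicates):
        scale = amplitude_uA * rng.lognormal(0.0, 0.3) if n_replicates > 1 else amplitude_uA
        noise = 1.0 + noise_cv * rng.standard_normal(conc.size) if noise_cv > 0 else 1.0
        resp = curve * scale * noise
        for s, y in zip(stimuli, resp):
            rows.append(
                {
                    "replicate_id": f"oocyte{r + 1:02d}",
                    "stimulus": float(s),
                    "stimulus_kind": stimulus_kind,
                    "response_uA": float(y),
                }
            )
    return DoseResponseTable(pd.DataFrame(rows), direction=direction)


# ---------------------------------------------------------------------------
# Behavior assays


def simulate_behavior(
    discharge_means: Mapping[str, float],
    capture_median_s: Mapping[str, float] | None = None,
    n_per_group: int = 8,
    reference_area_um2: float = 10_000.0,
    area_cv: float = 0.15,
    capture_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[DischargeCountTable, CaptureTimeTable]:
    """Poisson discharge counts and lognormal capture times per treatment.

    ``discharge_means`` gives the expected capsule count per reference area
    for each treatment; each animal's imaged area varies lognormally around
    the reference and its count is Poisson(mean x area / reference area).
    ``capture_median_s`` gives the median single-capture time; each animal's
    first/second/third capture times are the sorted order statistics of
    three lognormal draws.
    """
    rng = np.random.default_rng(seed)
    count_rows = []
    for treatment in sorted(discharge_means):
        mean = discharge_means[treatment]
        if mean < 0:
            raise ValueError(f"treatment {treatment!r}: negative mean count")
        for a in range(n_per_group):
            area = reference_area_um2 * rng.lognormal(0.0, area_cv)
            lam = mean * area / reference_area_um2
            count_rows.append(
                {
                    "animal_id": f"{treatment}-{a + 1:02d}",
                    "treatment": treatment,
                    "count": int(rng.poisson(lam)),
                    "area_um2": float(area),
                }
            )
    count_cols = ["animal_id", "treatment", "count", "area_um2"]
    counts = DischargeCountTable(pd.DataFrame(count_rows, columns=count_cols))

    capture_median_s = capture_median_s or {}
    time_rows = []
    for treatment in sorted(capture_median_s):
        median = capture_median_s[treatment]
        for a in range(n_per_group):
            draws = np.sort(rng.lognormal(math.log(median), capture_sigma, size=3))
            for event, t in zip(CaptureTimeTable.EVENT_ORDER, draws):
                time_rows.append(
                    {
                        "animal_id": f"{treatment}-{a + 1:02d}",
                        "treatment": treatment,
                        "event": event,
                        "time_s": float(t),
                    }
                )
    time_cols = ["animal_id", "treatment", "event", "time_s"]
    times = CaptureTimeTable(pd.DataFrame(time_rows, columns=time_cols))
    return counts, times
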