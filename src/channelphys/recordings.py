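"""TEVC trace containers, CSV/JSON I/O, and response-amplitude extraction.

Step recordings hold whole-cell current at a fixed holding potential with
labelled ligand-application windows (pH steps, blocker applications); ramp
recordings pair a voltage command with the measured current.  Current is in
microampere with inward current negative, the usual oocyte convention.

``measure_response`` reduces an application window to the quantities the
dose-response analysis consumes: a median pre-application baseline, the
sign-aware peak deviation, the sustained level over the final quarter of the
window, and a transient/sustained ratio used to flag biphasic responses
(a fast desensitizing transient riding on a sustained plateau).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ApplicationWindow",
    "StepRecording",
    "RampRecording",
    "ResponseMeasurement",
    "read_step_recording",
    "write_step_recording",
    "measure_response",
    "classify_biphasic",
]

#: classifier defaults: transient/sustained ratio and peak-position limits
BIPHASIC_RATIO_THRESHOLD = 1.5
BIPHASIC_PEAK_FRACTION = 0.20


@dataclass(frozen=True)
class ApplicationWindow:
    start_s: float
    end_s: float
    label: str
    stimulus: float | None = None  # pH or concentration, per metadata
    stimulus_kind: str = "pH"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"window {self.label!r}: end {self.end_s} <= start {self.start_s}")


@dataclass(frozen=True)
class StepRecording:
    """Current time-series at a fixed holding potential."""

    time_s: np.ndarray
    current_uA: np.ndarray
    holding_mV: float
    sampling_rate_hz: float
    windows: tuple[ApplicationWindow, ...] = ()
    oocyte_id: str = ""
    construct: str = ""
    solution_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        i = np.asarray(self.current_uA, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "current_uA", i)
        if t.ndim != 1 or t.size < 2 or t.shape != i.shape:
            raise ValueError("time and current must be matching 1-D arrays with >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time not strictly increasing at row {row + 1} (t={t[row]} s)")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid is not uniform")
        if not np.isclose(1.0 / dt[0], self.sampling_rate_hz, rtol=1e-3):
            raise ValueError(
                f"sampling rate {self.sampling_rate_hz} Hz inconsistent with grid step {dt[0]:g} s"
            )
        for w in self.windows:
            if w.start_s < t[0] - 1e-12 or w.end_s > t[-1] + 1e-12:
                raise ValueError(
                    f"window {w.label!r} [{w.start_s}, {w.end_s}] s extends outside the "
                    f"record [{t[0]}, {t[-1]}] s"
                )

    def window(self, label: str) -> ApplicationWindow:
        for w in self.windows:
            if w.label == label:
                return w
        raise KeyError(f"no application window labelled {label!r}")


@dataclass(frozen=True)
class RampRecording:
    """Paired voltage-command / current series for a voltage ramp."""

    time_s: np.ndarray
    voltage_mV: np.ndarray
    current_uA: np.ndarray
    ramp_spec: tuple[float, float, float]  # (V_start mV, V_end mV, duration s)
    condition: str = ""
    oocyte_id: str = ""
    solution_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.voltage_mV, dtype=float)
        i = np.asarray(self.current_uA, dtype=float)
        for name, arr in (("time_s", t), ("voltage_mV", v), ("current_uA", i)):
            object.__setattr__(self, name, arr)
        if not (t.shape == v.shape == i.shape) or t.ndim != 1:
            raise ValueError("time, voltage and current must be matching 1-D arrays")
        dv = np.diff(v)
        if not (np.all(dv >= 0) or np.all(dv <= 0)):
            raise ValueError("ramp voltage is not monotone")
        v0, v1, _dur = self.ramp_spec
        if abs(v[0] - v0) > 1.0 or abs(v[-1] - v1) > 1.0:
            raise ValueError(
                f"measured ramp endpoints ({v[0]:.2f}, {v[-1]:.2f}) mV deviate > 1 mV "
                f"from spec ({v0}, {v1}) mV"
            )


@dataclass(frozen=True)
class ResponseMeasurement:
    """Amplitudes extracted from one application window."""

    window_label: str
    baseline_uA: float
    peak_uA: float  # signed current at the peak deviation
    sustained_uA: float  # signed mean over the final 25% of the window
    transient_sustained_ratio: float  # NaN when the sustained deviation is ~0
    peak_time_fraction: float  # position of the peak within the window, [0, 1]
    biphasic: bool

    @property
    def peak_amplitude_uA(self) -> float:
        """Unsigned response amplitude at the peak."""
        return abs(self.peak_uA - self.baseline_uA)

    @property
    def sustained_amplitude_uA(self) -> float:
        return abs(self.sustained_uA - self.baseline_uA)


# ---------------------------------------------------------------------------
# I/O: CSV trace + JSON sidecar


def write_step_recording(rec: StepRecording, csv_path: str | Path) -> None:
    """Write the trace as `time_s,current_uA` CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": rec.time_s, "current_uA": rec.current_uA}).to_csv(
        csv_path, index=False, float_format="%.9g"
    )
    meta = {
        "holding_mV": rec.holding_mV,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "oocyte_id": rec.oocyte_id,
        "construct": rec.construct,
        "solution_labels": list(rec.solution_labels),
        "windows": [
            {
                "start_s": w.start_s,
                "end_s": w.end_s,
                "label": w.label,
                "stimulus": w.stimulus,
                "stimulus_kind": w.stimulus_kind,
            }
            for w in rec.windows
        ],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_step_recording(csv_path: str | Path) -> StepRecording:
    """Read a trace CSV and its JSON sidecar; malformed rows are reported by line."""
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    for key in ("holding_mV", "sampling_rate_hz", "windows"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required field {key!r}")
    df = pd.read_csv(csv_path)
    if not {"time_s", "current_uA"}.issubset(df.columns):
        raise ValueError(f"{csv_path}: header must contain time_s,current_uA")
    bad = df[["time_s", "current_uA"]].isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise ValueError(f"{csv_path}: malformed row at line {row}")
    t = df["time_s"].to_numpy()
    dup = np.flatnonzero(np.diff(t) <= 0)
    if dup.size:
        raise ValueError(
            f"{csv_path}: non-increasing time at line {dup[0] + 3} (t={t[dup[0] + 1]:g} s)"
        )
    windows = tuple(
        ApplicationWindow(
            w["start_s"], w["end_s"], w["label"], w.get("stimulus"), w.get("stimulus_kind", "pH")
        )
        for w in meta["windows"]
    )
    return StepRecording(
        time_s=t,
        current_uA=df["current_uA"].to_numpy(),
        holding_mV=meta["holding_mV"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        windows=windows,
        oocyte_id=meta.get("oocyte_id", ""),
        construct=meta.get("construct", ""),
        solution_labels=tuple(meta.get("solution_labels", ())),
    )


# ---------------------------------------------------------------------------
# Amplitude extraction


def measure_response(
    rec: StepRecording,
    window_label: str,
    baseline_s: float = 2.0,
    ratio_threshold: float = BIPHASIC_RATIO_THRESHOLD,
    peak_fraction: float = BIPHASIC_PEAK_FRACTION,
) -> ResponseMeasurement:
    """Extract baseline / peak / sustained amplitudes for one application window.

    Baseline is the median current over ``baseline_s`` seconds immediately
    before the window (clipped to the record start).  The peak is the sample
    with the largest absolute deviation from baseline inside the window, so
    inward (negative) responses are handled without sign conventions leaking
    into the caller.  Sustained is the mean over the final 25% of the window.
    """
    w = rec.window(window_label)
    t, i = rec.time_s, rec.current_uA
    in_win = (t >= w.start_s) & (t <= w.end_s)
    n_win = int(in_win.sum())
    if n_win < 4:
        raise ValueError(f"window {window_label!r} spans {n_win} samples; >= 4 required")
    pre = (t >= w.start_s - baseline_s) & (t < w.start_s)
    baseline = float(np.median(i[pre])) if pre.any() else float(i[in_win][0])

    win_t = t[in_win]
    win_i = i[in_win]
    dev = win_i - baseline
    k = int(np.argmax(np.abs(dev)))
    peak = float(win_i[k])
    peak_frac = float((win_t[k] - w.start_s) / (w.end_s - w.start_s))

    tail = win_i[int(np.ceil(0.75 * n_win)):]
    sustained = float(np.mean(tail))

    sus_dev = abs(sustained - baseline)
    peak_dev = abs(peak - baseline)
    ratio = peak_dev / sus_dev if sus_dev > 0 else float("nan")

    m = ResponseMeasurement(
        window_label=window_label,
        baseline_uA=baseline,
        peak_uA=peak,
        sustained_uA=sustained,
        transient_sustained_ratio=ratio,
        peak_time_fraction=peak_frac,
        biphasic=False,
    )
    return replace(m, biphasic=classify_biphasic(m, ratio_threshold, peak_fraction))


def classify_biphasic(
    m: ResponseMeasurement,
    ratio_threshold: float = BIPHASIC_RATIO_THRESHOLD,
    peak_fraction: float = BIPHASIC_PEAK_FRACTION,
) -> bool:
    """A response is biphasic when a large early transient decays to a plateau.

    Rule: transient/sustained ratio >= ``ratio_threshold`` AND the peak falls
    within the first ``peak_fraction`` of the window.
    """
    if not np.isfinite(m.transient_sustained_ratio):
        return False
    return (
        m.transient_sustained_ratio >= ratio_threshold
        and m.peak_time_fraction <= peak_fraction
    )
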