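"""Reversal potentials and GHK permeability ratios from I-V ramp data.

The workflow mirrors standard bi-ionic selectivity analysis in oocytes:

1. ramp currents recorded in a test solution (single dominant external
   cation) are corrected for background conductances by subtracting the
   pH 7.4 control ramp from the same cell;
2. the reversal potential ``Erev`` is read off the corrected I-V curve by
   linear interpolation between the two samples bracketing the zero
   crossing;
3. Erev shifts between test solutions give permeability ratios through the
   Goldman-Hodgkin-Katz voltage relations.

For two monovalent cations with the same internal milieu,

    P_Na/P_K = (a_K,o / a_Na,o) * exp(dErev * F / (R*T)),   dErev = E_Na - E_K

and for Ca2+ against Na+ (divalent-vs-monovalent bi-ionic form),

    P_Ca/P_Na = a_Na,o * (1 + exp(E_Ca*F/(R*T)))
                / (4 * a_Ca,o * exp(dErev*F/(R*T))),        dErev = E_Na - E_Ca

with external concentrations entered as Davies activities by default
(an ``activity_corrected`` toggle switches to nominal concentrations; the
two conventions differ materially for the divalent ratio).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, thermal_voltage_mV
from .recordings import RampRecording
from .solutions import SolutionComposition, activities

__all__ = [
    "IVCurve",
    "ErevEstimate",
    "PermeabilityResult",
    "iv_from_ramp",
    "subtract_background",
    "estimate_erev",
    "pna_over_pk",
    "pca_over_pna",
    "selectivity_report",
]

#: leading fraction of each ramp discarded before I-V construction
#: (settling of the capacitive onset transient)
RAMP_DISCARD_FRACTION = 0.02
MIN_OVERLAP_MV = 50.0


@dataclass(frozen=True)
class IVCurve:
    voltage_mV: np.ndarray
    current_uA: np.ndarray
    condition: str = ""
    background_condition: str | None = None
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_mV, dtype=float)
        i = np.asarray(self.current_uA, dtype=float)
        object.__setattr__(self, "voltage_mV", v)
        object.__setattr__(self, "current_uA", i)
        if v.shape != i.shape or v.ndim != 1 or v.size < 2:
            raise ValueError("voltage and current must be matching 1-D arrays")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltage grid must be strictly increasing")


@dataclass(frozen=True)
class ErevEstimate:
    erev_mV: float
    v_low_mV: float
    v_high_mV: float
    i_low_uA: float
    i_high_uA: float
    method: str = "linear-bracket"

    def __post_init__(self) -> None:
        if not (self.v_low_mV - 1e-9 <= self.erev_mV <= self.v_high_mV + 1e-9):
            raise ValueError("Erev outside its bracketing pair")


@dataclass(frozen=True)
class PermeabilityResult:
    kind: str  # "P_Na/P_K" or "P_Ca/P_Na"
    value: float
    delta_erev_mV: float
    activities_mM: Mapping[str, float]
    temperature_K: float
    activity_corrected: bool
    oocyte_id: str = ""


def iv_from_ramp(ramp: RampRecording, discard_fraction: float = RAMP_DISCARD_FRACTION) -> IVCurve:
    """Build an I-V curve from a ramp recording, ascending in voltage.

    The first ``discard_fraction`` of samples (capacitive onset) is dropped.
    """
    n = ramp.voltage_mV.size
    k = int(math.ceil(discard_fraction * n))
    v = ramp.voltage_mV[k:]
    i = ramp.current_uA[k:]
    order = np.argsort(v, kind="stable")
    v, i = v[order], i[order]
    keep = np.concatenate(([True], np.diff(v) > 0))  # drop duplicate voltages
    return IVCurve(v[keep], i[keep], condition=ramp.condition)


def subtract_background(test: IVCurve, control: IVCurve) -> IVCurve:
    """Subtract the control (pH 7.4) ramp current from the test ramp.

    The control is linearly interpolated onto the test voltage grid over
    their common span; an overlap below 50 mV is rejected as insufficient
    for reversal-potential work.
    """
    lo = max(test.voltage_mV[0], control.voltage_mV[0])
    hi = min(test.voltage_mV[-1], control.voltage_mV[-1])
    if hi - lo < MIN_OVERLAP_MV:
        raise ValueError(
            f"voltage overlap [{lo:.1f}, {hi:.1f}] mV is {hi - lo:.1f} mV; "
            f">= {MIN_OVERLAP_MV} mV required"
        )
    sel = (test.voltage_mV >= lo) & (test.voltage_mV <= hi)
    v = test.voltage_mV[sel]
    ctrl = np.interp(v, control.voltage_mV, control.current_uA)
    return IVCurve(
        v,
        test.current_uA[sel] - ctrl,
        condition=test.condition,
        background_condition=control.condition or "control",
        temperature_K=test.temperature_K,
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad: pad + x.size]
    return out


def estimate_erev(
    iv: IVCurve,
    smoothing_window: int = 5,
    search_mV: tuple[float, float] = (-70.0, 60.0),
) -> ErevEstimate:
    """Reversal potential by linear interpolation between the bracketing samples.

    A moving-average-smoothed copy locates the zero crossing (suppressing
    noise-induced spurious crossings); the interpolation itself always uses
    the raw bracketing samples.  If several crossings survive smoothing the
    one nearest the zero of a least-squares line through the whole curve is
    taken.
    """
    sel = (iv.voltage_mV >= search_mV[0]) & (iv.voltage_mV <= search_mV[1])
    v = iv.voltage_mV[sel]
    i = iv.current_uA[sel]
    if v.size < 2:
        raise ValueError("fewer than 2 samples in the search window")
    if np.all(i == 0):
        raise ValueError("degenerate I-V curve: identically zero in the search window")

    smooth = _moving_average(i, smoothing_window)
    crossings = _zero_crossings(smooth)
    if not crossings:
        crossings = _zero_crossings(i)
    if not crossings:
        raise ValueError("no reversal in window: current does not change sign")

    if len(crossings) > 1:
        slope, intercept = np.polyfit(v, i, 1)
        target = -intercept / slope if slope != 0 else 0.5 * (v[0] + v[-1])
        crossings.sort(key=lambda k: abs(0.5 * (v[k] + v[k + 1]) - target))
    k = crossings[0]

    # interpolate on the nearest RAW opposite-sign pair around the chosen crossing
    k = _nearest_raw_crossing(i, k)
    if k is None:
        raise ValueError("no reversal in window: current does not change sign")
    i0, i1 = i[k], i[k + 1]
    erev = v[k] - i0 * (v[k + 1] - v[k]) / (i1 - i0)
    return ErevEstimate(float(erev), float(v[k]), float(v[k + 1]), float(i0), float(i1))


def _zero_crossings(x: np.ndarray) -> list[int]:
    s = np.sign(x)
    # treat exact zeros as belonging to the following sign
    for k in range(1, s.size):
        if s[k] == 0:
            s[k] = s[k - 1]
    return [int(k) for k in np.flatnonzero(s[:-1] * s[1:] < 0)]


def _nearest_raw_crossing(i: np.ndarray, k: int) -> int | None:
    raw = _zero_crossings(i)
    if not raw:
        # the chosen sample itself may be an exact zero
        zeros = np.flatnonzero(i == 0)
        if zeros.size:
            j = int(zeros[np.argmin(np.abs(zeros - k))])
            return j if j < i.size - 1 else j - 1
        return None
    return min(raw, key=lambda j: abs(j - k))


# ---------------------------------------------------------------------------
# GHK permeability ratios


def pna_over_pk(
    a_na_mM: float,
    a_k_mM: float,
    e_na_mV: float,
    e_k_mV: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    activity_corrected: bool = True,
    oocyte_id: str = "",
) -> PermeabilityResult:
    """Monovalent permeability ratio from the Erev shift between bi-ionic ramps."""
    if a_na_mM <= 0 or a_k_mM <= 0:
        raise ValueError("ion activities must be positive")
    delta = e_na_mV - e_k_mV
    value = (a_k_mM / a_na_mM) * math.exp(delta / thermal_voltage_mV(temperature_K))
    return PermeabilityResult(
        kind="P_Na/P_K",
        value=value,
        delta_erev_mV=delta,
        activities_mM={"Na+": a_na_mM, "K+": a_k_mM},
        temperature_K=temperature_K,
        activity_corrected=activity_corrected,
        oocyte_id=oocyte_id,
    )


def pca_over_pna(
    a_na_mM: float,
    a_ca_mM: float,
    e_ca_mV: float,
    e_na_mV: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    activity_corrected: bool = True,
    oocyte_id: str = "",
) -> PermeabilityResult:
    """Divalent/monovalent permeability ratio from Na+ and Ca2+ bi-ionic Erevs."""
    if a_na_mM <= 0 or a_ca_mM <= 0:
        raise ValueError("ion activities must be positive")
    vt = thermal_voltage_mV(temperature_K)
    delta = e_na_mV - e_ca_mV
    value = a_na_mM * (1.0 + math.exp(e_ca_mV / vt)) / (4.0 * a_ca_mM * math.exp(delta / vt))
    return PermeabilityResult(
        kind="P_Ca/P_Na",
        value=value,
        delta_erev_mV=delta,
        activities_mM={"Na+": a_na_mM, "Ca2+": a_ca_mM},
        temperature_K=temperature_K,
        activity_corrected=activity_corrected,
        oocyte_id=oocyte_id,
    )


# ---------------------------------------------------------------------------
# Batch report


def selectivity_report(
    ramps: Iterable[RampRecording],
    solutions: Mapping[str, SolutionComposition],
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    activity_corrected: bool = True,
    smoothing_window: int = 5,
) -> tuple[list[PermeabilityResult], pd.DataFrame]:
    """Chain background subtraction -> Erev -> GHK ratios over a set of ramps.

    Pairing convention: for each oocyte, a test ramp with ``condition`` C
    requires a control ramp with ``condition`` C + "_control" from the same
    oocyte (the pH 7.4 background ramp).  Test conditions are "na", "k",
    "ca"; each condition's ``solution_label`` must resolve in ``solutions``.
    P_Na/P_K is computed per oocyte with both "na" and "k"; P_Ca/P_Na per
    oocyte with both "na" and "ca".

    Returns per-oocyte results and a summary table (mean, S.D., n per ratio).
    """
    by_oocyte: dict[str, dict[str, RampRecording]] = {}
    for r in ramps:
        by_oocyte.setdefault(r.oocyte_id, {})[r.condition] = r

    ion_of = {"na": "Na+", "k": "K+", "ca": "Ca2+"}
    results: list[PermeabilityResult] = []
    for oocyte, recs in sorted(by_oocyte.items()):
        erevs: dict[str, float] = {}
        acts: dict[str, float] = {}
        for cond in ("na", "k", "ca"):
            if cond not in recs:
                continue
            ctrl_key = f"{cond}_control"
            if ctrl_key not in recs:
                raise ValueError(f"oocyte {oocyte!r}: missing control ramp for {cond!r}")
            test_iv = iv_from_ramp(recs[cond])
            ctrl_iv = iv_from_ramp(recs[ctrl_key])
            corrected = subtract_background(test_iv, ctrl_iv)
            erevs[cond] = estimate_erev(corrected, smoothing_window=smoothing_window).erev_mV
            sol = solutions[recs[cond].solution_label]
            ion = ion_of[cond]
            if activity_corrected:
                acts[cond] = activities(sol).activity_mM[ion]
            else:
                acts[cond] = next(s.mM for s in sol.species if s.name == ion)
        if "na" in erevs and "k" in erevs:
            results.append(
                pna_over_pk(
                    acts["na"], acts["k"], erevs["na"], erevs["k"],
                    temperature_K, activity_corrected, oocyte,
                )
            )
        if "na" in erevs and "ca" in erevs:
            results.append(
                pca_over_pna(
                    acts["na"], acts["ca"], erevs["ca"], erevs["na"],
                    temperature_K, activity_corrected, oocyte,
                )
            )

    rows = []
    for kind in ("P_Na/P_K", "P_Ca/P_Na"):
        vals = np.array([r.value for r in results if r.kind == kind])
        if vals.size == 0:
            continue
        rows.append(
            {
                "ratio": kind,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                "n": vals.size,
            }
        )
    return results, pd.DataFrame(rows)
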