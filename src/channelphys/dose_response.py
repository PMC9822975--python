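"""Hill-equation characterization of concentration-response data.

Activation (proton-gated currents vs. [H+]) is fitted per replicate with

    R(c) = R_max * c**n / (c**n + EC50**n)

and inhibition (amiloride, diminazene, extracellular Ca2+) with a
partial-block Hill form

    R(c) = R_top * [ f_res + (1 - f_res) / (1 + (c / IC50)**n) ]

where ``f_res`` is the residual unblocked fraction (fixed to 0 for full
block) and ``R_top``, the unblocked response, absorbs normalization error
when the lowest tested concentration already blocks slightly.  Half-maximal constants are optimized as log10 parameters, which
linearizes the search across decades; proton data are additionally reported
as pH50 = -log10(EC50).  Each replicate (oocyte) is fitted independently and
parameters are then summarized as mean +/- S.D. (+/- S.E.M.) across
replicates, so the reported spread includes biological variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "DoseResponseTable",
    "HillFit",
    "ph_to_concentration",
    "normalize",
    "fit_activation",
    "fit_inhibition",
    "summarize",
]

HILL_N_BOUNDS = (0.1, 10.0)


def ph_to_concentration(pH: float) -> float:
    """[H+] in molar from pH."""
    if not 0 < pH < 14:
        raise ValueError(f"pH {pH} outside (0, 14)")
    return 10.0 ** (-pH)


@dataclass(frozen=True)
class DoseResponseTable:
    """Long-format concentration-response measurements.

    ``data`` columns: replicate_id, stimulus, stimulus_kind ("pH"|"molar"),
    response_uA.  pH stimuli are converted to molar [H+] on access via
    :meth:`concentrations`.
    """

    data: pd.DataFrame
    direction: Literal["activation", "inhibition"]
    normalized: bool = False

    REQUIRED = ("replicate_id", "stimulus", "stimulus_kind", "response_uA")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"dose-response table missing columns {sorted(missing)}")
        if self.direction not in ("activation", "inhibition"):
            raise ValueError(f"direction must be activation|inhibition, got {self.direction!r}")
        n_levels = self.data["stimulus"].nunique()
        if n_levels < 4:
            raise ValueError(f"need >= 4 distinct stimulus levels for fitting, got {n_levels}")

    def concentrations(self) -> np.ndarray:
        """Stimulus in molar, converting pH rows to [H+]."""
        df = self.data
        conc = df["stimulus"].to_numpy(dtype=float).copy()
        is_ph = df["stimulus_kind"].to_numpy() == "pH"
        conc[is_ph] = np.array([ph_to_concentration(p) for p in conc[is_ph]])
        return conc

    @property
    def is_ph_data(self) -> bool:
        return bool((self.data["stimulus_kind"] == "pH").all())

    def replicates(self) -> list[str]:
        return sorted(self.data["replicate_id"].unique())


@dataclass(frozen=True)
class ReplicateFit:
    replicate_id: str
    half_max_M: float  # EC50 or IC50
    hill_n: float
    r_max: float
    f_res: float | None
    converged: bool
    rss: float
    message: str = ""

    @property
    def ph50(self) -> float:
        return -math.log10(self.half_max_M)


@dataclass(frozen=True)
class HillFit:
    """Per-replicate Hill parameters with across-replicate summary."""

    direction: str
    replicate_fits: tuple[ReplicateFit, ...]
    summary: pd.DataFrame  # parameter x (mean, sd, sem, n)
    is_ph_data: bool = False

    @property
    def half_max_M(self) -> float:
        """Mean EC50/IC50 across converged replicates (geometric, via log10)."""
        return 10.0 ** self.summary.loc["log10_half_max", "mean"]

    @property
    def ph50(self) -> float:
        return -self.summary.loc["log10_half_max", "mean"]

    @property
    def n_converged(self) -> int:
        return sum(f.converged for f in self.replicate_fits)


def normalize(table: DoseResponseTable, reference: Literal["max"] = "max") -> DoseResponseTable:
    """Divide each replicate's responses by its own maximal absolute response.

    Normalized responses are unsigned (inward-current amplitudes become
    positive), making fits invariant to expression-level scaling.
    """
    df = table.data.copy()
    out = []
    for rep, grp in df.groupby("replicate_id", sort=False):
        ref = grp["response_uA"].abs().max()
        if ref == 0 or not np.isfinite(ref):
            raise ValueError(f"replicate {rep!r}: zero/invalid reference response")
        grp = grp.copy()
        grp["response_uA"] = grp["response_uA"].abs() / ref
        out.append(grp)
    return DoseResponseTable(pd.concat(out, ignore_index=True), table.direction, normalized=True)


# ---------------------------------------------------------------------------
# Hill models (concentration space, log10 half-max parameterization)


def _hill_activation(c, log10_ec50, hill_n, r_max):
    ec50 = 10.0 ** log10_ec50
    cn = np.power(c, hill_n)
    return r_max * cn / (cn + ec50**hill_n)


def _hill_inhibition(c, log10_ic50, hill_n, f_res, r_top):
    # r_top is the unblocked response; ~1 for data normalized to a true
    # zero-blocker control, slightly above the observed maximum when the
    # lowest tested concentration already blocks a little
    ic50 = 10.0 ** log10_ic50
    return r_top * (f_res + (1.0 - f_res) / (1.0 + np.power(c / ic50, hill_n)))


def _init_half_max(conc: np.ndarray, resp: np.ndarray, direction: str) -> float:
    """log10 of the stimulus bracketing half-max, by log-linear interpolation."""
    order = np.argsort(conc)
    c, r = conc[order], resp[order]
    target = 0.5 * (r.min() + r.max())
    sign = 1.0 if direction == "activation" else -1.0
    rr = sign * r
    tt = sign * target
    for k in range(len(c) - 1):
        lo, hi = min(rr[k], rr[k + 1]), max(rr[k], rr[k + 1])
        if lo <= tt <= hi and rr[k + 1] != rr[k]:
            frac = (tt - rr[k]) / (rr[k + 1] - rr[k])
            return math.log10(c[k]) + frac * (math.log10(c[k + 1]) - math.log10(c[k]))
    return float(np.median(np.log10(c)))


def _fit_one_replicate(
    conc: np.ndarray,
    resp: np.ndarray,
    direction: str,
    f_res_mode: Literal["free", "zero"],
    rep_id: str,
) -> ReplicateFit:
    if np.any(conc <= 0):
        raise ValueError(f"replicate {rep_id!r}: non-positive stimulus concentration")
    log10_c50_init = _init_half_max(conc, resp, direction)
    span = (math.log10(conc.min()) - 3.0, math.log10(conc.max()) + 3.0)
    if direction == "activation":
        model = Model(_hill_activation)
        params = model.make_params(
            log10_ec50=dict(value=log10_c50_init, min=span[0], max=span[1]),
            hill_n=dict(value=1.0, min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1]),
            r_max=dict(value=float(np.max(resp)), min=1e-9),
        )
    else:
        model = Model(_hill_inhibition)
        params = model.make_params(
            log10_ic50=dict(value=log10_c50_init, min=span[0], max=span[1]),
            hill_n=dict(value=1.0, min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1]),
            f_res=dict(value=0.1, min=0.0, max=1.0, vary=f_res_mode == "free"),
            r_top=dict(value=float(np.max(resp)), min=1e-9),
        )
        if f_res_mode == "zero":
            params["f_res"].value = 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(resp, params, c=conc, method="leastsq", xtol=1e-10, ftol=1e-12)

    key = "log10_ec50" if direction == "activation" else "log10_ic50"
    half_max = 10.0 ** result.params[key].value
    rss = float(np.sum(result.residual**2))
    converged = bool(result.success)
    # direction sanity: the Hill family is monotone by construction, so data
    # trending the wrong way are flagged from their own rank correlation
    order = np.argsort(conc)
    ranks_r = np.argsort(np.argsort(resp[order]))
    ranks_c = np.arange(conc.size)
    trend = float(np.corrcoef(ranks_c, ranks_r)[0, 1]) if conc.size > 2 else 0.0
    if (direction == "activation" and trend < 0) or (direction == "inhibition" and trend > 0):
        converged = False
    return ReplicateFit(
        replicate_id=rep_id,
        half_max_M=half_max,
        hill_n=float(result.params["hill_n"].value),
        r_max=float(
            result.params["r_max" if direction == "activation" else "r_top"].value
        ),
        f_res=float(result.params["f_res"].value) if direction == "inhibition" else None,
        converged=converged,
        rss=rss,
        message=result.message or "",
    )


def _summarize_fits(fits: list[ReplicateFit], direction: str) -> pd.DataFrame:
    ok = [f for f in fits if f.converged]
    params: dict[str, list[float]] = {
        "log10_half_max": [math.log10(f.half_max_M) for f in ok],
        "hill_n": [f.hill_n for f in ok],
    }
    if direction == "activation":
        params["r_max"] = [f.r_max for f in ok]
    else:
        if any(f.f_res is not None for f in ok):
            params["f_res"] = [f.f_res for f in ok if f.f_res is not None]
    rows = {}
    for name, vals in params.items():
        arr = np.asarray(vals, dtype=float)
        n = arr.size
        rows[name] = {
            "mean": arr.mean() if n else np.nan,
            "sd": arr.std(ddof=1) if n > 1 else np.nan,
            "sem": arr.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan,
            "n": n,
        }
    return pd.DataFrame(rows).T


def _fit(table: DoseResponseTable, direction: str, f_res_mode: Literal["free", "zero"]) -> HillFit:
    if table.direction != direction:
        raise ValueError(f"table direction {table.direction!r}; expected {direction!r}")
    work = table if table.normalized else normalize(table)
    conc_all = work.concentrations()
    fits: list[ReplicateFit] = []
    for rep in work.replicates():
        mask = (work.data["replicate_id"] == rep).to_numpy()
        fit = _fit_one_replicate(
            conc_all[mask], work.data["response_uA"].to_numpy()[mask], direction, f_res_mode, rep
        )
        if not fit.converged:
            warnings.warn(
                f"replicate {rep!r}: {direction} fit did not converge "
                f"({fit.message or 'wrong-direction/degenerate data'}); excluded from summary",
                stacklevel=3,
            )
        fits.append(fit)
    return HillFit(
        direction=direction,
        replicate_fits=tuple(fits),
        summary=_summarize_fits(fits, direction),
        is_ph_data=table.is_ph_data,
    )


def fit_activation(table: DoseResponseTable) -> HillFit:
    """Per-replicate Hill activation fit; proton data also reported as pH50."""
    return _fit(table, "activation", f_res_mode="zero")


def fit_inhibition(table: DoseResponseTable, f_res: Literal["free", "zero"] = "free") -> HillFit:
    """Per-replicate partial-block inhibition fit.

    ``f_res="zero"`` forces complete block (residual fraction pinned to 0),
    appropriate for blockers that fully silence the current at saturation.
    """
    return _fit(table, "inhibition", f_res_mode=f_res)


def summarize(values: np.ndarray | list[float]) -> dict[str, float]:
    """mean / S.D. / S.E.M. / n for a set of replicate parameter estimates.

    With a single replicate only the mean is defined; S.D. and S.E.M. are NaN.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("no values to summarize")
    out = {"mean": float(arr.mean()), "n": n}
    if n >= 2:
        sd = float(arr.std(ddof=1))
        out["sd"] = sd
        out["sem"] = sd / math.sqrt(n)
    else:
        out["sd"] = float("nan")
        out["sem"] = float("nan")
    return out
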