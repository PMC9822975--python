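"""Statistics for cnidocyte-discharge and prey-capture assays.

Discharged-capsule counts per imaged area are compared across treatments
(pH, prey extract, diminazene, genotype) with the classical parametric
toolkit: unpaired equal-variance Student's t for two groups, one-way ANOVA
for more, followed by Bonferroni or Tukey HSD pairwise comparisons, all at
alpha = 0.05.  The test statistics are computed from the textbook sums of
squares (scipy provides only the p-value distributions), so the module can
be validated against an independent reference implementation.

Counts observed over different imaged areas are put on a common footing as
densities (count / area), optionally rescaled to a common reference area.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DischargeCountTable",
    "CaptureTimeTable",
    "TestResult",
    "discharge_density",
    "unpaired_t",
    "one_way_anova",
    "posthoc",
    "discharge_anova_pipeline",
]

ALPHA = 0.05


@dataclass(frozen=True)
class DischargeCountTable:
    """Rows: animal_id, treatment, count (discharged capsules), area_um2."""

    data: pd.DataFrame

    REQUIRED = ("animal_id", "treatment", "count", "area_um2")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"discharge table missing columns {sorted(missing)}")
        if (self.data["count"] < 0).any():
            raise ValueError("capsule counts must be >= 0")
        if (self.data["area_um2"] <= 0).any():
            raise ValueError("imaged area must be > 0")

    def groups(self, value: str = "count") -> dict[str, np.ndarray]:
        return {
            str(k): g[value].to_numpy(dtype=float)
            for k, g in self.data.groupby("treatment", sort=True)
        }


@dataclass(frozen=True)
class CaptureTimeTable:
    """Rows: animal_id, treatment, event (first|second|third), time_s."""

    data: pd.DataFrame

    REQUIRED = ("animal_id", "treatment", "event", "time_s")
    EVENT_ORDER = ("first", "second", "third")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"capture table missing columns {sorted(missing)}")
        for (animal, _), grp in self.data.groupby(["animal_id", "treatment"]):
            times = grp.set_index("event")["time_s"]
            seq = [times.get(e) for e in self.EVENT_ORDER if e in times.index]
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"animal {animal!r}: capture times not ordered")


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    comparison: tuple[str, ...] = ()
    adjustment: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def discharge_density(counts, areas_um2) -> np.ndarray:
    """Capsules per um^2 for each observation."""
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas_um2, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("imaged area must be > 0")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    return counts / areas


def unpaired_t(x, y, two_tailed: bool = True, welch: bool = False) -> TestResult:
    """Two-sample Student's t (pooled variance by default; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)) if se2 > 0 else nx + ny - 2
    else:
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = pooled * (1.0 / nx + 1.0 / ny)
        df = nx + ny - 2
    if se2 == 0:
        warnings.warn("zero variance in both samples; p reported as 1", stacklevel=2)
        return TestResult("t", 0.0, (float(df),), 1.0)
    t = (mx - my) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df) if two_tailed else stats.t.sf(t, df)
    return TestResult("t-welch" if welch else "t", float(t), (float(df),), float(min(p, 1.0)))


def _anova_sums(groups: Sequence[np.ndarray]) -> tuple[float, float, int, int]:
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = sum(g.sum() for g in groups) / n_total
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return ssb, ssw, k - 1, n_total - k


def one_way_anova(groups: Sequence) -> TestResult:
    """One-way fixed-effects ANOVA from the classical sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    ssb, ssw, df_b, df_w = _anova_sums(groups)
    if ssw == 0:
        if ssb == 0:
            warnings.warn("all groups constant and equal; F undefined, p reported as 1", stacklevel=2)
            return TestResult("anova", 0.0, (float(df_b), float(df_w)), 1.0)
        return TestResult("anova", float("inf"), (float(df_b), float(df_w)), 0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    return TestResult("anova", float(f), (float(df_b), float(df_w)), float(p))


def posthoc(
    groups: dict[str, np.ndarray] | Sequence,
    method: Literal["bonferroni", "tukey"] = "bonferroni",
) -> list[TestResult]:
    """All pairwise comparisons after a one-way ANOVA.

    Bonferroni: pairwise pooled-variance t-tests with p multiplied by the
    number of pairs (capped at 1).  Tukey(-Kramer): studentized-range test on
    the ANOVA's within-group mean square.
    """
    if not isinstance(groups, dict):
        groups = {str(i): np.asarray(g, dtype=float) for i, g in enumerate(groups)}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("post-hoc comparisons need >= 2 groups")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every group needs n >= 2")
    pairs = list(itertools.combinations(labels, 2))
    results: list[TestResult] = []

    if method == "bonferroni":
        m = len(pairs)
        for a, b in pairs:
            base = unpaired_t(groups[a], groups[b])
            results.append(
                TestResult(
                    "t",
                    base.statistic,
                    base.df,
                    min(1.0, base.p_value * m),
                    comparison=(a, b),
                    adjustment="bonferroni",
                )
            )
        return results

    if method != "tukey":
        raise ValueError(f"unknown post-hoc method {method!r}")

    arr = [groups[lab] for lab in labels]
    _, ssw, _, df_w = _anova_sums(arr)
    msw = ssw / df_w
    k = len(labels)
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        if msw == 0:
            warnings.warn("zero within-group variance; Tukey p reported as 1", stacklevel=2)
            q = 0.0 if ga.mean() == gb.mean() else float("inf")
            p = 1.0 if q == 0.0 else 0.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / ga.size + 1.0 / gb.size))
            q = abs(ga.mean() - gb.mean()) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        results.append(
            TestResult("tukey-q", float(q), (float(k), float(df_w)), min(1.0, p),
                       comparison=(a, b), adjustment="tukey")
        )
    return results


def discharge_anova_pipeline(
    table: DischargeCountTable,
    posthoc_method: Literal["bonferroni", "tukey"] = "bonferroni",
    normalize_area: bool = False,
    reference_area_um2: float = 10_000.0,
) -> tuple[TestResult, list[TestResult]]:
    """ANOVA across treatments, then protected pairwise comparisons.

    Post-hoc comparisons run only when the omnibus ANOVA rejects at
    alpha = 0.05 (protected testing); otherwise an empty list is returned.
    ``normalize_area`` rescales each count to a common reference area
    (density x reference area) before testing.
    """
    df = table.data
    if normalize_area:
        values = discharge_density(df["count"], df["area_um2"]) * reference_area_um2
        work = df.assign(value=values)
    else:
        work = df.assign(value=df["count"].astype(float))
    groups = {
        str(k): g["value"].to_numpy(dtype=float) for k, g in work.groupby("treatment", sort=True)
    }
    omnibus = one_way_anova(list(groups.values()))
    comparisons = posthoc(groups, posthoc_method) if omnibus.significant else []
    return omnibus, comparisons
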