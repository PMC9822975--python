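"""Recording solutions: ionic strength, Davies activity coefficients, ion activities.

A :class:`SolutionComposition` lists the fully dissociated ionic species of a
bench recipe (salts expanded to their constituent ions, e.g. 1.8 mM CaCl2
contributes 1.8 mM Ca2+ and 3.6 mM Cl-).  From that the module computes the
ionic strength

    I = 0.5 * sum_i c_i * z_i**2        (c_i in molar)

and the single-ion activity coefficient via the Davies equation, the empirical
extension of Debye-Hueckel theory valid to I ~ 0.5 M:

    log10 f_i = -0.509 * z_i**2 * ( sqrt(I)/(1 + sqrt(I)) - 0.2*I )

Activities (f_i * c_i) are what enter the Goldman-Hodgkin-Katz permeability
equations in :mod:`channelphys.selectivity`.  Neutral buffer components
(HEPES, MES, EGTA, PVP) carry no charge bookkeeping here and are excluded
from the ionic strength by default; an ionized fraction can be supplied for
them explicitly.  Proton activity is always 10**(-pH) molar -- pH is already
an activity scale and is never Davies-corrected.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "IonSpecies",
    "SolutionComposition",
    "ActivityResult",
    "ionic_strength",
    "davies_log10_gamma",
    "activities",
    "proton_activity_M",
    "load_solution_library",
    "save_solution_library",
    "default_solution_library",
]

DAVIES_A = 0.509
CHARGE_IMBALANCE_TOL_MM = 1.0


@dataclass(frozen=True)
class IonSpecies:
    """A dissolved ion: signed valence ``z`` and concentration in mM."""

    name: str
    z: int
    mM: float

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError(
                f"species {self.name!r} has valence 0; neutral components "
                "belong in SolutionComposition.neutral, not among the ions"
            )
        if self.mM < 0:
            raise ValueError(f"species {self.name!r} has negative concentration {self.mM} mM")


@dataclass(frozen=True)
class SolutionComposition:
    """A named recording solution as fully dissociated ionic species.

    ``neutral`` lists uncharged components (buffers, chelators) kept for
    provenance only.  A charge imbalance above ``CHARGE_IMBALANCE_TOL_MM``
    triggers a warning rather than an error: published recipes routinely
    omit the counter-ions of pH titrants.
    """

    label: str
    species: tuple[IonSpecies, ...]
    neutral: tuple[str, ...] = ()
    pH: float | None = None

    def __init__(
        self,
        label: str,
        species: Iterable[IonSpecies],
        neutral: Iterable[str] = (),
        pH: float | None = None,
    ) -> None:
        species = tuple(species)
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError(f"solution {label!r}: duplicate species names in {names}")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "neutral", tuple(neutral))
        object.__setattr__(self, "pH", pH)
        imbalance = sum(s.z * s.mM for s in species)
        if abs(imbalance) > CHARGE_IMBALANCE_TOL_MM:
            warnings.warn(
                f"solution {label!r}: net charge imbalance {imbalance:+.2f} mM "
                f"exceeds {CHARGE_IMBALANCE_TOL_MM} mM (titrant counter-ions omitted?)",
                stacklevel=3,
            )

    def proton_activity_M(self) -> float:
        if self.pH is None:
            raise ValueError(f"solution {self.label!r} has no pH recorded")
        return proton_activity_M(self.pH)


@dataclass(frozen=True)
class ActivityResult:
    """Ionic strength (molar) plus per-species log10 coefficient and activity (mM)."""

    solution_label: str
    ionic_strength_M: float
    log10_gamma: Mapping[str, float]
    activity_mM: Mapping[str, float]

    def gamma(self, name: str) -> float:
        return 10.0 ** self.log10_gamma[name]


def ionic_strength(solution: SolutionComposition) -> float:
    """Ionic strength in molar: 0.5 * sum c_i z_i^2 over all charged species."""
    return 0.5 * sum((s.mM * 1e-3) * s.z**2 for s in solution.species)


def davies_log10_gamma(z: int, ionic_strength_M: float) -> float:
    """log10 of the single-ion Davies activity coefficient.

    The z1*z2 product of the two-ion form reduces to z**2 for a single ion.
    Exactly 0 at I = 0 for any valence.
    """
    if ionic_strength_M < 0:
        raise ValueError(f"ionic strength must be >= 0, got {ionic_strength_M}")
    if ionic_strength_M == 0:
        return 0.0
    sqrt_i = math.sqrt(ionic_strength_M)
    return -DAVIES_A * z**2 * (sqrt_i / (1.0 + sqrt_i) - 0.2 * ionic_strength_M)


def activities(solution: SolutionComposition) -> ActivityResult:
    """Davies-corrected activity of every species at the solution's own ionic strength."""
    i_molar = ionic_strength(solution)
    log10_gamma = {s.name: davies_log10_gamma(s.z, i_molar) for s in solution.species}
    activity = {s.name: 10.0 ** log10_gamma[s.name] * s.mM for s in solution.species}
    return ActivityResult(solution.label, i_molar, log10_gamma, activity)


def proton_activity_M(pH: float) -> float:
    """Proton activity in molar, 10^(-pH); never Davies-corrected."""
    if not 0 < pH < 14:
        raise ValueError(f"pH {pH} outside (0, 14)")
    return 10.0 ** (-pH)


# ---------------------------------------------------------------------------
# YAML solution library


def _solution_from_entry(entry: Mapping) -> SolutionComposition:
    species = tuple(IonSpecies(s["ion"], int(s["z"]), float(s["mM"])) for s in entry["species"])
    return SolutionComposition(
        label=entry["label"],
        species=species,
        neutral=tuple(entry.get("neutral", ())),
        pH=entry.get("pH"),
    )


def load_solution_library(path: str | Path) -> dict[str, SolutionComposition]:
    """Load a YAML solution library into a dict keyed by label."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    solutions = [_solution_from_entry(e) for e in doc["solutions"]]
    return {s.label: s for s in solutions}


def save_solution_library(solutions: Iterable[SolutionComposition], path: str | Path) -> None:
    doc = {
        "solutions": [
            {
                "label": s.label,
                "species": [{"ion": sp.name, "z": sp.z, "mM": sp.mM} for sp in s.species],
                "neutral": list(s.neutral),
                "pH": s.pH,
            }
            for s in solutions
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_solution_library() -> dict[str, SolutionComposition]:
    """The named bench recipes shipped with the package (see data/solutions.yaml)."""
    ref = importlib.resources.files("channelphys") / "data" / "solutions.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_solution_library(path)
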