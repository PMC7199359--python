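"""Macronutrient energy accounting for meals.

Total metabolisable energy (kJ) and percent energy per macronutrient,
computed from gram amounts with per-gram energy factors.  The default
factors (17 kJ/g carbohydrate, 37 kJ/g fat, 17 kJ/g protein, 8 kJ/g dietary
fibre) are the FSANZ-style metabolisable-energy constants used on
Australian food labels; fibre is included in total energy.

The bundled :func:`reference_meal` is the standard mixed meal (wholemeal
bread, butter, peanut butter, chocolate milk) against which test meals are
normalised: ~2000 kJ with carbohydrate/fat/protein at roughly 41/40/16 %
energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

__all__ = [
    "MealComposition",
    "EnergyFactors",
    "EnergyProfile",
    "energy_profile",
    "aggregate_components",
    "reference_meal",
    "DEFAULT_ENERGY_FACTORS",
    "MealError",
]


class MealError(ValueError):
    """Raised for invalid meal compositions or degenerate energy requests."""


# gram fields that carry energy, in reporting order
ENERGY_MACROS = ("carbohydrate", "fat", "protein", "fibre")

#: Tolerance (g) for sub-class consistency checks (label rounding).
_SUBCLASS_TOL_G = 0.5


@dataclass(frozen=True)
class MealComposition:
    """Gram amounts of macronutrients and sub-classes for one meal or
    component.

    Sub-class fields (sugar/starch, fat fractions) are informational; only
    ``carbohydrate_g``, ``fat_g``, ``protein_g`` and ``fibre_g`` enter the
    energy computation.
    """

    carbohydrate_g: float = 0.0
    sugar_g: float = 0.0
    starch_g: float = 0.0
    fat_g: float = 0.0
    saturated_g: float = 0.0
    polyunsaturated_g: float = 0.0
    monounsaturated_g: float = 0.0
    fibre_g: float = 0.0
    protein_g: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "label":
                continue
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise MealError(f"{f.name} must be a finite number, got {v!r}")
            if v < 0:
                raise MealError(f"{f.name} must be >= 0, got {v!r}")
        if self.sugar_g > 0 and self.starch_g > 0:
            if self.sugar_g + self.starch_g > self.carbohydrate_g + _SUBCLASS_TOL_G:
                raise MealError(
                    "sugar_g + starch_g exceeds carbohydrate_g beyond the "
                    f"{_SUBCLASS_TOL_G} g tolerance"
                )
        fat_sub = self.saturated_g + self.polyunsaturated_g + self.monounsaturated_g
        if fat_sub > 0 and fat_sub > self.fat_g + _SUBCLASS_TOL_G:
            raise MealError(
                "fat sub-classes exceed fat_g beyond the "
                f"{_SUBCLASS_TOL_G} g tolerance"
            )

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "MealComposition":
        """Build from a dict whose keys are the gram field names (plus
        optional ``label``); unknown keys are rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise MealError(f"unknown meal composition keys: {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]


@dataclass(frozen=True)
class EnergyFactors:
    """Per-gram metabolisable energy (kJ/g) for the energy-carrying
    macronutrients."""

    carbohydrate: float = 17.0
    fat: float = 37.0
    protein: float = 17.0
    fibre: float = 8.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise MealError(f"energy factor {f.name} must be > 0, got {v!r}")


DEFAULT_ENERGY_FACTORS = EnergyFactors()


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class EnergyProfile:
    """Total energy and percent-energy breakdown of a meal.

    ``percent_energy`` sums to 100; ``rounded_percent`` rounds each entry
    to the nearest integer (ties away from zero), the convention used on
    printed nutrition panels.
    """

    total_kJ: float
    percent_energy: dict[str, float]
    rounded_percent: dict[str, int]


def energy_profile(
    meal: MealComposition,
    factors: EnergyFactors = DEFAULT_ENERGY_FACTORS,
) -> EnergyProfile:
    """Compute total kJ and percent energy per macronutrient.

    total_kJ = sum over {carbohydrate, fat, protein, fibre} of grams x
    factor; percent_energy[m] = 100 x grams_m x factor_m / total_kJ.

    Raises
    ------
    MealError
        If every energy-carrying gram field is zero (percentages
        undefined).
    """
    kj = {
        m: getattr(meal, f"{m}_g") * getattr(factors, m) for m in ENERGY_MACROS
    }
    total = sum(kj.values())
    if total <= 0:
        raise MealError(
            f"meal {meal.label!r} carries no energy; percent energy is undefined"
        )
    percent = {m: 100.0 * v / total for m, v in kj.items()}
    rounded = {m: _round_half_away(p) for m, p in percent.items()}
    return EnergyProfile(total_kJ=total, percent_energy=percent, rounded_percent=rounded)


def aggregate_components(components: Iterable[MealComposition]) -> MealComposition:
    """Field-wise sum of component compositions (e.g. bread + butter +
    peanut butter + chocolate milk -> combined meal); labels are joined
    with ' + '."""
    comps = list(components)
    if not comps:
        raise MealError("cannot aggregate an empty component list")
    totals: dict[str, float] = {}
    for f in fields(MealComposition):
        if f.name == "label":
            continue
        totals[f.name] = sum(getattr(c, f.name) for c in comps)
    label = " + ".join(c.label for c in comps if c.label)
    return MealComposition(label=label, **totals)


def reference_meal() -> MealComposition:
    """The combined reference meal: 2 slices wholemeal bread, 7 g butter,
    11 g peanut butter, 250 mL chocolate milk.

    Gram amounts: 50 g carbohydrate (26 sugar, 24 starch), 22 g fat
    (11 saturated, 1 polyunsaturated, 8 monounsaturated), 6 g dietary
    fibre, 19 g protein.  With the default energy factors this meal
    computes to ~2035 kJ with fat 40%, protein 16% and fibre 2% of energy.
    """
    return MealComposition(
        carbohydrate_g=50.0,
        sugar_g=26.0,
        starch_g=24.0,
        fat_g=22.0,
        saturated_g=11.0,
        polyunsaturated_g=1.0,
        monounsaturated_g=8.0,
        fibre_g=6.0,
        protein_g=19.0,
        label="reference meal (wholemeal bread, butter, peanut butter, chocolate milk)",
    )
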