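"""Canonical units and conversions for serum analytes.

Every quantity entering the GlucoTRIG computation is first brought onto a
single canonical scale: insulin in pmol/L, triglycerides and glucose in
mmol/L.  Raw-unit values never mix with canonical ones downstream; the
conversion constants live in :class:`UnitConfig` and are overridable
(different immunoassay conventions use slightly different insulin factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Analyte",
    "Quantity",
    "UnitConfig",
    "DEFAULT_UNIT_CONFIG",
    "to_canonical",
    "convert",
    "UnitError",
]


class UnitError(ValueError):
    """Raised for an unknown unit, an illegal unit/analyte pairing, or an
    invalid value."""


#: Analyte names accepted throughout the package.
ANALYTES = ("insulin", "triglycerides", "glucose")

#: Legal units per analyte; the first entry is the canonical unit.
_LEGAL_UNITS: dict[str, tuple[str, ...]] = {
    "insulin": ("pmol/L", "mU/L"),
    "triglycerides": ("mmol/L", "mg/dL"),
    "glucose": ("mmol/L", "mg/dL"),
}

Analyte = str  # one of ANALYTES


@dataclass(frozen=True)
class UnitConfig:
    """Conversion constants onto the canonical scale.

    Parameters
    ----------
    insulin_mU_to_pmol
        Multiplier taking insulin mU/L to pmol/L.  6.945 is the standard
        clinical-chemistry constant; some assay conventions use values up
        to ~7.2, hence the override.
    tg_mgdl_to_mmol
        Divisor taking triglycerides mg/dL to mmol/L (molar mass based).
    glucose_mgdl_to_mmol
        Divisor taking glucose mg/dL to mmol/L.
    """

    insulin_mU_to_pmol: float = 6.945
    tg_mgdl_to_mmol: float = 88.5
    glucose_mgdl_to_mmol: float = 18.0

    def __post_init__(self) -> None:
        for name in ("insulin_mU_to_pmol", "tg_mgdl_to_mmol", "glucose_mgdl_to_mmol"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise UnitError(f"conversion constant {name!r} must be a positive finite number, got {v!r}")


DEFAULT_UNIT_CONFIG = UnitConfig()


@dataclass(frozen=True)
class Quantity:
    """A serum measurement with explicit units.

    Attributes
    ----------
    value
        Non-negative finite concentration.
    unit
        One of the legal units for the analyte (see module docstring).
    analyte
        ``"insulin"``, ``"triglycerides"`` or ``"glucose"``.
    """

    value: float
    unit: str
    analyte: Analyte

    def __post_init__(self) -> None:
        if self.analyte not in _LEGAL_UNITS:
            raise UnitError(
                f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}"
            )
        if self.unit not in _LEGAL_UNITS[self.analyte]:
            raise UnitError(
                f"unit {self.unit!r} is not legal for analyte {self.analyte!r}; "
                f"expected one of {_LEGAL_UNITS[self.analyte]}"
            )
        if not (isinstance(self.value, (int, float)) and math.isfinite(self.value)):
            raise UnitError(f"value must be finite, got {self.value!r}")
        if self.value < 0:
            raise UnitError(
                f"{self.analyte} value must be >= 0, got {self.value!r}"
            )


def canonical_unit(analyte: Analyte) -> str:
    """Return the canonical unit for *analyte*."""
    try:
        return _LEGAL_UNITS[analyte][0]
    except KeyError:
        raise UnitError(f"unknown analyte {analyte!r}") from None


def _factor_to_canonical(analyte: Analyte, unit: str, config: UnitConfig) -> float:
    """Multiplier taking (analyte, unit) to the canonical unit."""
    if unit == canonical_unit(analyte):
        return 1.0
    if analyte == "insulin" and unit == "mU/L":
        return config.insulin_mU_to_pmol
    if analyte == "triglycerides" and unit == "mg/dL":
        return 1.0 / config.tg_mgdl_to_mmol
    if analyte == "glucose" and unit == "mg/dL":
        return 1.0 / config.glucose_mgdl_to_mmol
    raise UnitError(f"unit {unit!r} is not legal for analyte {analyte!r}")


def to_canonical(q: Quantity, config: UnitConfig = DEFAULT_UNIT_CONFIG) -> Quantity:
    """Convert *q* to the canonical unit for its analyte.

    Idempotent: a quantity already in canonical units is returned with the
    same value.  Round-tripping through :func:`convert` recovers the input
    to within 1e-9 relative.
    """
    factor = _factor_to_canonical(q.analyte, q.unit, config)
    if factor == 1.0:
        return q
    return Quantity(q.value * factor, canonical_unit(q.analyte), q.analyte)


def convert(q: Quantity, unit: str, config: UnitConfig = DEFAULT_UNIT_CONFIG) -> Quantity:
    """Convert *q* to an arbitrary legal *unit* for its analyte."""
    canon = to_canonical(q, config)
    back = _factor_to_canonical(q.analyte, unit, config)  # validates unit
    if unit == canonical_unit(q.analyte):
        return canon
    return Quantity(canon.value / back, unit, q.analyte)
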