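"""The GlucoTRIG index.

GlucoTRIG scores one meal challenge from two serum draws, fasting (0 min)
and postprandial (default 180 min)::

    GlucoTRIG = TG_180 * INS_180  -  TG_0 * INS_0

with insulin in pmol/L and triglycerides in mmol/L, so the index carries
units pmol*mmol/L^2.  A meal whose insulin and triglycerides have returned
to baseline by the postprandial draw scores ~0 (healthy); persistent joint
elevation scores high; negative values (postprandial product below the
fasting product) are legal and retained.  Test meals are reported as a
fraction of the reference meal's value.

The index is deliberately a two-fixed-draw difference, not an area under
the curve: samples must sit exactly at the configured times and are never
interpolated.  Glucose is carried alongside as a side outcome but never
enters the index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MetabolicSample",
    "VisitRecord",
    "GlucoTRIGResult",
    "compute_glucotrig",
    "relative_glucotrig",
    "mean_change",
    "VisitError",
]

#: Default sampling times (minutes) for the baseline and postprandial draws.
DEFAULT_TIMES = (0, 180)


class VisitError(ValueError):
    """Raised for structurally invalid samples or visit records."""


def _check_conc(name: str, v: float | None, optional: bool = False) -> None:
    if v is None:
        if optional:
            return
        raise VisitError(f"{name} is required")
    if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
        raise VisitError(f"{name} must be a finite number >= 0, got {v!r}")


@dataclass(frozen=True)
class MetabolicSample:
    """One serum draw, in canonical units (insulin pmol/L, triglycerides
    mmol/L, glucose mmol/L)."""

    time_min: int
    insulin: float
    triglycerides: float
    glucose: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.time_min, int) and self.time_min >= 0):
            raise VisitError(f"time_min must be an integer >= 0, got {self.time_min!r}")
        _check_conc("insulin", self.insulin)
        _check_conc("triglycerides", self.triglycerides)
        _check_conc("glucose", self.glucose, optional=True)


@dataclass(frozen=True)
class VisitRecord:
    """One subject x one meal x one test day: a baseline and a
    postprandial sample."""

    subject_id: str
    visit: int
    baseline: MetabolicSample
    postprandial: MetabolicSample
    meal_label: str = ""

    def __post_init__(self) -> None:
        if not (isinstance(self.visit, int) and self.visit >= 1):
            raise VisitError(f"visit must be a positive integer, got {self.visit!r}")
        if self.baseline.time_min >= self.postprandial.time_min:
            raise VisitError(
                f"subject {self.subject_id!r} visit {self.visit}: baseline time "
                f"{self.baseline.time_min} must precede postprandial time "
                f"{self.postprandial.time_min}"
            )


@dataclass(frozen=True)
class GlucoTRIGResult:
    """Per-visit index value with the two insulin x triglyceride products
    it is the difference of.  Units: pmol*mmol/L^2."""

    subject_id: str
    visit: int
    value: float
    baseline_product: float
    postprandial_product: float


def compute_glucotrig(visit: VisitRecord) -> GlucoTRIGResult:
    """Compute the GlucoTRIG index for one visit.

    value = TG_post * INS_post - TG_base * INS_base, both products
    recorded.  Inputs must already be canonical (pmol/L, mmol/L).
    """
    if visit.baseline is None or visit.postprandial is None:  # defensive; dataclass enforces
        raise VisitError(
            f"subject {visit.subject_id!r} visit {visit.visit}: missing sample"
        )
    p0 = visit.baseline.triglycerides * visit.baseline.insulin
    p1 = visit.postprandial.triglycerides * visit.postprandial.insulin
    return GlucoTRIGResult(
        subject_id=visit.subject_id,
        visit=visit.visit,
        value=p1 - p0,
        baseline_product=p0,
        postprandial_product=p1,
    )


def relative_glucotrig(test_value: float, reference_value: float) -> float:
    """Express a test meal's index as a fraction of the reference meal's.

    Raises
    ------
    VisitError
        If ``reference_value`` is zero (normalisation undefined).
    """
    if reference_value == 0:
        raise VisitError("reference GlucoTRIG value is 0; normalisation undefined")
    return test_value / reference_value


def mean_change(records: Sequence[VisitRecord], analyte: str) -> float:
    """Mean postprandial-minus-baseline change of *analyte* across visits.

    ``analyte`` is one of ``insulin``, ``triglycerides``, ``glucose``.
    Used for the side outcomes (e.g. the mean 180-0 min glucose change);
    glucose must be present in every sample or the call is rejected.
    """
    if analyte not in ("insulin", "triglycerides", "glucose"):
        raise VisitError(f"unknown analyte {analyte!r}")
    if not records:
        raise VisitError("mean_change requires at least one record")
    deltas = []
    for r in records:
        v0 = getattr(r.baseline, analyte)
        v1 = getattr(r.postprandial, analyte)
        if v0 is None or v1 is None:
            raise VisitError(
                f"subject {r.subject_id!r} visit {r.visit}: {analyte} missing"
            )
        deltas.append(v1 - v0)
    return sum(deltas) / len(deltas)
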