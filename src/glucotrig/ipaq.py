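"""IPAQ-style physical activity scoring.

Converts weekly frequency x duration by intensity into MET-minutes per
week and classifies the week as low / moderate / high following the
official IPAQ scoring protocol.  MET multipliers: walking 3.3, moderate
4.0, vigorous 8.0.

Categories (evaluated high first):

high
    >= 3 vigorous days with total activity >= 1500 MET-min/week, or
    activity on >= 7 days (summed across intensities) with total
    >= 3000 MET-min/week.
moderate
    >= 3 vigorous days of >= 20 min/day, or >= 5 days of moderate
    activity and/or walking of >= 30 min/day, or >= 5 days of any
    combination with total >= 600 MET-min/week.
low
    anything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ActivityProfile", "classify_activity", "MET_VALUES", "ActivityError"]

#: MET multiplier per intensity (official long-form scoring protocol).
MET_VALUES = {"walking": 3.3, "moderate": 4.0, "vigorous": 8.0}

INTENSITIES = ("walking", "moderate", "vigorous")


class ActivityError(ValueError):
    """Raised for out-of-range activity inputs."""


@dataclass(frozen=True)
class ActivityProfile:
    """One week of self-reported activity: days/week and minutes/day per
    intensity."""

    walking_days: int = 0
    walking_min_per_day: float = 0.0
    moderate_days: int = 0
    moderate_min_per_day: float = 0.0
    vigorous_days: int = 0
    vigorous_min_per_day: float = 0.0

    def __post_init__(self) -> None:
        for intensity in INTENSITIES:
            d = getattr(self, f"{intensity}_days")
            m = getattr(self, f"{intensity}_min_per_day")
            if not (isinstance(d, int) and 0 <= d <= 7):
                raise ActivityError(
                    f"{intensity}_days must be an integer in 0..7, got {d!r}"
                )
            if not (isinstance(m, (int, float)) and math.isfinite(m) and m >= 0):
                raise ActivityError(
                    f"{intensity}_min_per_day must be >= 0, got {m!r}"
                )

    def met_min_week(self, intensity: str) -> float:
        """MET-min/week for one intensity: days x min/day x MET."""
        if intensity not in INTENSITIES:
            raise ActivityError(f"unknown intensity {intensity!r}")
        return (
            getattr(self, f"{intensity}_days")
            * getattr(self, f"{intensity}_min_per_day")
            * MET_VALUES[intensity]
        )

    @property
    def total_met_min_week(self) -> float:
        return sum(self.met_min_week(i) for i in INTENSITIES)

    @property
    def total_days(self) -> int:
        """Activity days summed across intensities (may exceed 7: several
        intensities can fall on the same calendar day)."""
        return self.walking_days + self.moderate_days + self.vigorous_days


def classify_activity(profile: ActivityProfile) -> str:
    """Classify one week of activity as ``"low"``, ``"moderate"`` or
    ``"high"``.

    Exactly one category is returned; increasing any minutes (or days)
    value never lowers the category.
    """
    total = profile.total_met_min_week

    # high: vigorous-driven or any-combination criterion
    if profile.vigorous_days >= 3 and profile.vigorous_min_per_day > 0 and total >= 1500:
        return "high"
    if profile.total_days >= 7 and total >= 3000:
        return "high"

    # moderate: three alternative clauses
    if profile.vigorous_days >= 3 and profile.vigorous_min_per_day >= 20:
        return "moderate"
    mod_walk_days = (profile.moderate_days if profile.moderate_min_per_day >= 30 else 0) + (
        profile.walking_days if profile.walking_min_per_day >= 30 else 0
    )
    if mod_walk_days >= 5:
        return "moderate"
    if profile.total_days >= 5 and total >= 600:
        return "moderate"

    return "low"
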