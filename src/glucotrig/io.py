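"""Cohort table readers/writers and run configuration.

The canonical on-disk cohort format is a long CSV (UTF-8, comma-separated,
header mandatory, dot decimals)::

    subject_id,visit,time_min,analyte,value,unit
    S001,1,0,insulin,44.1,pmol/L
    S001,1,0,triglycerides,0.8,mmol/L
    ...

A wide variant (one column per analyte, units supplied via the run
configuration) is also accepted; long is canonical and is what the writer
emits.  All values are canonicalised on read; rows at times other than
the two configured sampling times are retained in the returned frame but
flagged unused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .core import DEFAULT_TIMES, MetabolicSample, VisitRecord, VisitError
from .meal_energy import EnergyFactors, MealComposition, DEFAULT_ENERGY_FACTORS
from .units import DEFAULT_UNIT_CONFIG, Quantity, UnitConfig, UnitError, canonical_unit, to_canonical

__all__ = [
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "read_meal_composition",
    "read_activity_profiles",
    "CohortFormatError",
]

LONG_COLUMNS = ["subject_id", "visit", "time_min", "analyte", "value", "unit"]
ANALYTE_COLUMNS = ["insulin", "triglycerides", "glucose"]


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the schema contract."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide configuration.

    sampling_times must be strictly increasing and exactly two are used
    for the index (baseline, postprandial).  ``reference_value`` is the
    reference meal's index against which relative values are reported.
    """

    units: UnitConfig = field(default_factory=UnitConfig)
    energy_factors: EnergyFactors = field(default_factory=EnergyFactors)
    sampling_times: tuple[int, int] = DEFAULT_TIMES
    alpha: float = 0.05
    reference_value: float = 19.0
    outlier_rule: bool = True
    # units assumed for wide-format files without explicit unit columns
    insulin_unit: str = "pmol/L"
    tg_unit: str = "mmol/L"
    glucose_unit: str = "mmol/L"

    def __post_init__(self) -> None:
        if len(self.sampling_times) != 2:
            raise CohortFormatError(
                "exactly two sampling times (baseline, postprandial) are required"
            )
        if not self.sampling_times[0] < self.sampling_times[1]:
            raise CohortFormatError("sampling times must be strictly increasing")
        if not 0 < self.alpha < 1:
            raise CohortFormatError(f"alpha must be in (0, 1), got {self.alpha!r}")


def _canonical_value(analyte: str, value: float, unit: str, units: UnitConfig) -> float:
    return to_canonical(Quantity(value, unit, analyte), units).value


def _long_from_wide(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    unit_for = {
        "insulin": config.insulin_unit,
        "triglycerides": config.tg_unit,
        "glucose": config.glucose_unit,
    }
    present = [a for a in ANALYTE_COLUMNS if a in df.columns]
    if not present:
        raise CohortFormatError(
            f"unrecognised cohort schema: columns {list(df.columns)}; expected "
            f"long columns {LONG_COLUMNS} or wide columns with at least one of "
            f"{ANALYTE_COLUMNS}"
        )
    long = df.melt(
        id_vars=["subject_id", "visit", "time_min"],
        value_vars=present,
        var_name="analyte",
        value_name="value",
    ).dropna(subset=["value"])
    long["unit"] = long["analyte"].map(unit_for)
    return long


def read_cohort(
    path: str | Path, config: RunConfig = RunConfig()
) -> tuple[list[VisitRecord], pd.DataFrame]:
    """Read a cohort CSV (long or wide) into VisitRecords.

    Returns ``(records, unused)`` where *unused* holds the rows at
    sampling times other than the configured pair (retained, flagged, not
    used by the index).

    Raises
    ------
    CohortFormatError
        On duplicate (subject, visit, time, analyte) keys, unknown units,
        or a subject x visit missing a required time point or analyte;
        the message lists the offending rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in ("subject_id", "visit", "time_min") if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"cohort file lacks required columns {missing_cols}")
    if not set(LONG_COLUMNS).issubset(df.columns):
        df = _long_from_wide(df, config)
    df = df[LONG_COLUMNS].copy()
    df["visit"] = df["visit"].astype(int)
    df["time_min"] = df["time_min"].astype(int)

    dup = df.duplicated(subset=["subject_id", "visit", "time_min", "analyte"], keep=False)
    if dup.any():
        offending = df.loc[dup, ["subject_id", "visit", "time_min", "analyte"]]
        raise CohortFormatError(
            "duplicate (subject_id, visit, time_min, analyte) rows:\n"
            + offending.to_string(index=False)
        )

    try:
        df["canonical_value"] = [
            _canonical_value(a, v, u, config.units)
            for a, v, u in zip(df["analyte"], df["value"], df["unit"])
        ]
    except UnitError as e:
        raise CohortFormatError(str(e)) from e

    t0, t1 = config.sampling_times
    used = df[df["time_min"].isin((t0, t1))]
    unused = df[~df["time_min"].isin((t0, t1))].copy()
    unused["unused"] = True

    records: list[VisitRecord] = []
    problems: list[str] = []
    for (sid, visit), grp in used.groupby(["subject_id", "visit"], sort=True):
        samples: dict[int, dict[str, float]] = {}
        for _, row in grp.iterrows():
            samples.setdefault(row["time_min"], {})[row["analyte"]] = row["canonical_value"]
        for t in (t0, t1):
            if t not in samples:
                problems.append(f"subject {sid!r} visit {visit}: no rows at {t} min")
            else:
                for required in ("insulin", "triglycerides"):
                    if required not in samples[t]:
                        problems.append(
                            f"subject {sid!r} visit {visit}: {required} missing at {t} min"
                        )
        if problems:
            continue
        records.append(
            VisitRecord(
                subject_id=str(sid),
                visit=int(visit),
                baseline=MetabolicSample(
                    t0,
                    insulin=samples[t0]["insulin"],
                    triglycerides=samples[t0]["triglycerides"],
                    glucose=samples[t0].get("glucose"),
                ),
                postprandial=MetabolicSample(
                    t1,
                    insulin=samples[t1]["insulin"],
                    triglycerides=samples[t1]["triglycerides"],
                    glucose=samples[t1].get("glucose"),
                ),
            )
        )
    if problems:
        raise CohortFormatError("cohort file incomplete:\n" + "\n".join(problems))
    return records, unused


def cohort_to_frame(records: Sequence[VisitRecord]) -> pd.DataFrame:
    """Long-format canonical-unit frame for a list of VisitRecords."""
    rows = []
    for r in records:
        for sample in (r.baseline, r.postprandial):
            for analyte in ANALYTE_COLUMNS:
                v = getattr(sample, analyte)
                if v is None:
                    continue
                rows.append(
                    {
                        "subject_id": r.subject_id,
                        "visit": r.visit,
                        "time_min": sample.time_min,
                        "analyte": analyte,
                        "value": v,
                        "unit": canonical_unit(analyte),
                    }
                )
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def write_cohort(records: Sequence[VisitRecord], path: str | Path) -> None:
    """Write VisitRecords as the canonical long CSV (round-trips through
    :func:`read_cohort` for canonical-unit data)."""
    cohort_to_frame(records).to_csv(path, index=False)


def read_meal_composition(path: str | Path) -> tuple[MealComposition, list[MealComposition]]:
    """Read a meal composition config (YAML or JSON — YAML is a superset).

    Either a flat mapping of gram fields, or a mapping with a
    ``components`` list of such mappings which are aggregated field-wise.
    Returns ``(combined, components)``; *components* is empty for flat
    files.
    """
    from .meal_energy import aggregate_components

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise CohortFormatError(f"meal composition file {path} must be a mapping")
    if "components" in data:
        comps = [MealComposition.from_mapping(c) for c in data["components"]]
        combined = aggregate_components(comps)
        if "label" in data:
            combined = replace(combined, label=str(data["label"]))
        return combined, comps
    return MealComposition.from_mapping(dict(data)), []


def read_activity_profiles(path: str | Path):
    """Read an activity CSV (subject_id, intensity, days_per_week,
    minutes_per_day) into per-subject ActivityProfiles."""
    from .ipaq import ActivityProfile, INTENSITIES

    df = pd.read_csv(path)
    required = {"subject_id", "intensity", "days_per_week", "minutes_per_day"}
    if not required.issubset(df.columns):
        raise CohortFormatError(
            f"activity file lacks required columns {sorted(required - set(df.columns))}"
        )
    profiles: dict[str, ActivityProfile] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        kwargs: dict[str, object] = {}
        for _, row in grp.iterrows():
            intensity = row["intensity"]
            if intensity not in INTENSITIES:
                raise CohortFormatError(
                    f"subject {sid!r}: unknown intensity {intensity!r}"
                )
            kwargs[f"{intensity}_days"] = int(row["days_per_week"])
            kwargs[f"{intensity}_min_per_day"] = float(row["minutes_per_day"])
        profiles[str(sid)] = ActivityProfile(**kwargs)  # type: ignore[arg-type]
    return profiles
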