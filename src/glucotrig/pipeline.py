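"""End-to-end cohort analysis: per-visit index, cohort roll-ups, ANOVA.

Mirrors the reporting structure of a crossover reference-meal study:
per-visit mean +/- SEM of the index, the grand value (mean of per-subject
means), the between-visit coefficient of variation, a repeated-measures
ANOVA across visits with Bonferroni post hoc tests, an optional
mean +/- 2 SD subject-level outlier exclusion, and the relative value
against the configured reference index.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GlucoTRIGResult, VisitRecord, compute_glucotrig, relative_glucotrig
from .io import RunConfig
from .stats import (
    CohortSummary,
    OutlierReport,
    RmAnovaResult,
    StatsError,
    between_visit_cv,
    exclude_outliers,
    rm_anova,
    summarize,
)

__all__ = ["PipelineReport", "run_pipeline", "results_frame", "PipelineError"]

logger = logging.getLogger("glucotrig")


class PipelineError(ValueError):
    """Raised when the cohort cannot be analysed (stage named in message)."""


@dataclass
class PipelineReport:
    """Machine-readable cohort report; ``render()`` gives the
    human-readable version."""

    n_subjects: int
    n_visits: int
    per_visit: dict[int, CohortSummary]
    grand: CohortSummary
    cv_percent: float | None
    anova: RmAnovaResult | None
    outliers: OutlierReport | None
    relative_value: float | None
    excluded_subjects: list[str] = field(default_factory=list)
    config_hash: str = ""

    def to_dict(self) -> dict:
        d = {
            "n_subjects": self.n_subjects,
            "n_visits": self.n_visits,
            "per_visit": {
                str(v): asdict(s) for v, s in sorted(self.per_visit.items())
            },
            "grand": asdict(self.grand),
            "cv_percent": self.cv_percent,
            "relative_value": self.relative_value,
            "excluded_subjects": self.excluded_subjects,
            "config_hash": self.config_hash,
        }
        if self.anova is not None:
            d["anova"] = {
                "f_stat": self.anova.f_stat,
                "df_effect": self.anova.df_effect,
                "df_error": self.anova.df_error,
                "p_value": self.anova.p_value,
                "degenerate": self.anova.degenerate,
                "posthoc": [
                    {"pair": list(pair), "raw_p": raw, "bonferroni_p": adj}
                    for pair, raw, adj in self.anova.posthoc
                ],
            }
        if self.outliers is not None:
            d["outlier_bounds"] = [self.outliers.lower_bound, self.outliers.upper_bound]
        return d

    def render(self) -> str:
        lines = [
            f"GlucoTRIG cohort report  (n = {self.n_subjects} subjects, "
            f"{self.n_visits} visits)"
        ]
        for v, s in sorted(self.per_visit.items()):
            lines.append(
                f"  visit {v}: mean {s.mean:8.3f}  SEM {s.sem:6.3f}  (n = {s.n})"
            )
        g = self.grand
        lines.append(f"  grand value: {g.mean:.3f} +/- {g.sem:.3f} (mean +/- SEM)")
        if self.cv_percent is not None:
            lines.append(f"  between-visit CV: {self.cv_percent:.1f}%")
        if self.anova is not None:
            a = self.anova
            flag = "  [degenerate: zero error mean square]" if a.degenerate else ""
            lines.append(
                f"  rmANOVA across visits: F({a.df_effect},{a.df_error}) = "
                f"{a.f_stat:.4g}, p = {a.p_value:.4g}{flag}"
            )
        if self.excluded_subjects:
            lines.append(
                f"  excluded subjects (mean +/- 2 SD rule): {self.excluded_subjects}"
            )
        if self.relative_value is not None:
            lines.append(
                f"  relative to reference meal: {self.relative_value:.3f}"
            )
        return "\n".join(lines)


def results_frame(records: Sequence[VisitRecord]) -> pd.DataFrame:
    """Per-visit GlucoTRIG table: subject_id, visit, value and the two
    products."""
    res = [compute_glucotrig(r) for r in records]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in res],
            "visit": [r.visit for r in res],
            "baseline_product": [r.baseline_product for r in res],
            "postprandial_product": [r.postprandial_product for r in res],
            "glucotrig": [r.value for r in res],
        }
    )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "units": asdict(config.units),
            "energy_factors": asdict(config.energy_factors),
            "sampling_times": list(config.sampling_times),
            "alpha": config.alpha,
            "reference_value": config.reference_value,
            "outlier_rule": config.outlier_rule,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(
    records: Sequence[VisitRecord],
    config: RunConfig = RunConfig(),
    manual_exclusions: Sequence[str] = (),
) -> PipelineReport:
    """Analyse a cohort of VisitRecords.

    Steps: per-visit index -> optional subject-level outlier exclusion
    (per-subject mean index, mean +/- 2 SD rule, applied once alongside
    any *manual_exclusions*) -> per-visit and grand summaries ->
    between-visit CV -> rmANOVA across visits (complete, balanced
    subjects only).
    """
    if not records:
        raise PipelineError("stage=index: empty cohort")
    df = results_frame(records)
    if df.duplicated(subset=["subject_id", "visit"]).any():
        raise PipelineError("stage=index: duplicate subject x visit records")

    # manual exclusions (e.g. abnormal pathology) first
    manual = [s for s in manual_exclusions if s in set(df["subject_id"])]
    df = df[~df["subject_id"].isin(manual)]
    if df.empty:
        raise PipelineError("stage=exclusion: all subjects excluded")

    outlier_report: OutlierReport | None = None
    excluded = list(manual)
    subject_means = df.groupby("subject_id", sort=True)["glucotrig"].mean()
    if config.outlier_rule and len(subject_means) >= 3:
        outlier_report = exclude_outliers(list(subject_means.items()))
        rule_excluded = [sid for sid, _ in outlier_report.excluded]
        excluded.extend(rule_excluded)
        df = df[~df["subject_id"].isin(rule_excluded)]

    visits = sorted(df["visit"].unique())
    per_visit: dict[int, CohortSummary] = {}
    for v in visits:
        vals = df.loc[df["visit"] == v, "glucotrig"].to_numpy()
        try:
            per_visit[v] = summarize(vals)
        except StatsError as e:
            raise PipelineError(f"stage=summaries: visit {v}: {e}") from e

    subject_means = df.groupby("subject_id", sort=True)["glucotrig"].mean()
    try:
        grand = summarize(subject_means.to_numpy())
    except StatsError as e:
        raise PipelineError(f"stage=summaries: grand: {e}") from e

    cv = None
    if len(visits) >= 2:
        visit_means = [per_visit[v].mean for v in visits]
        try:
            cv = between_visit_cv(visit_means)
        except StatsError:
            cv = None  # mean of visit means is 0; CV undefined

    anova: RmAnovaResult | None = None
    if len(visits) >= 2:
        wide = df.pivot(index="subject_id", columns="visit", values="glucotrig")
        complete = wide.dropna()
        if len(complete) >= 2:
            anova = rm_anova(complete.to_numpy())
            if anova.degenerate:
                logger.warning("rmANOVA degenerate: zero error mean square")

    relative = None
    if config.reference_value:
        relative = relative_glucotrig(grand.mean, config.reference_value)

    report = PipelineReport(
        n_subjects=int(df["subject_id"].nunique()),
        n_visits=len(visits),
        per_visit=per_visit,
        grand=grand,
        cv_percent=cv,
        anova=anova,
        outliers=outlier_report,
        relative_value=relative,
        excluded_subjects=excluded,
        config_hash=_config_hash(config),
    )
    logger.info(
        "pipeline run: config=%s n_subjects=%d n_visits=%d excluded=%s",
        report.config_hash,
        report.n_subjects,
        report.n_visits,
        excluded,
    )
    return report
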