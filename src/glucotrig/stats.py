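"""Cohort statistics for the crossover design.

Implements the study-style statistical layer: mean +/- SEM summaries, a
single-pass mean +/- 2 SD outlier rule, between-visit coefficient of
variation, and a one-way repeated-measures ANOVA (subject as the blocking
factor) with Bonferroni-corrected paired post hoc tests.

Conventions: sample (n-1) standard deviation throughout; no sphericity
correction (a documented limitation); with a zero error mean square the
ANOVA is flagged degenerate rather than silently reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CohortSummary",
    "OutlierReport",
    "RmAnovaResult",
    "summarize",
    "exclude_outliers",
    "rm_anova",
    "between_visit_cv",
    "StatsError",
]


class StatsError(ValueError):
    """Raised for degenerate or malformed statistical inputs."""


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- SEM style summary of a sample.

    ``cv_percent`` is 100*sd/|mean|, ``None`` when the mean is zero
    (undefined) or n < 2.
    """

    n: int
    mean: float
    sd: float
    sem: float
    cv_percent: float | None = None


def summarize(values: Sequence[float]) -> CohortSummary:
    """Mean, sample sd, SEM = sd/sqrt(n) and CV of a list of values.

    n >= 1 is required; with n == 1 the sd/sem are reported as 0 is not
    meaningful, so n >= 2 is required for dispersion and a single value is
    rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise StatsError("cannot summarize an empty sample")
    if x.size < 2:
        raise StatsError("sd/SEM need n >= 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    sem = sd / math.sqrt(x.size)
    cv = 100.0 * sd / abs(mean) if mean != 0 else None
    return CohortSummary(n=int(x.size), mean=mean, sd=sd, sem=sem, cv_percent=cv)


@dataclass(frozen=True)
class OutlierReport:
    """Partition of (id, value) pairs by the mean +/- 2 SD rule."""

    retained: list[tuple[Hashable, float]]
    excluded: list[tuple[Hashable, float]]
    lower_bound: float
    upper_bound: float


def exclude_outliers(
    values: Sequence[tuple[Hashable, float]], n_sd: float = 2.0
) -> OutlierReport:
    """Single-pass outlier exclusion: bounds = mean +/- n_sd * sd of ALL
    input values, then partition.

    The rule is non-iterative (bounds are never recomputed after
    exclusion) and order-invariant.  Intended for per-subject mean index
    values, one value per subject.
    """
    pairs = list(values)
    if len(pairs) < 3:
        raise StatsError("outlier rule needs n >= 3 (sd unreliable below that)")
    x = np.array([v for _, v in pairs], dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    retained = [(i, float(v)) for i, v in pairs if lo <= v <= hi]
    excluded = [(i, float(v)) for i, v in pairs if not (lo <= v <= hi)]
    return OutlierReport(retained=retained, excluded=excluded, lower_bound=lo, upper_bound=hi)


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way repeated-measures ANOVA with Bonferroni post hoc tests.

    ``posthoc`` holds one entry per condition pair: ((i, j), raw paired-t
    p, Bonferroni-adjusted p).  ``degenerate`` flags a zero error mean
    square (all residual variation absorbed by subjects/conditions).
    """

    f_stat: float
    df_effect: int
    df_error: int
    p_value: float
    posthoc: list[tuple[tuple[int, int], float, float]]
    degenerate: bool = False


def rm_anova(matrix: Sequence[Sequence[float]] | np.ndarray) -> RmAnovaResult:
    """Within-subjects one-way ANOVA on a complete subjects x conditions
    matrix.

    Decomposition: SS_total = SS_subjects + SS_conditions + SS_error with
    df_effect = k-1 and df_error = (k-1)(n-1); F = MS_conditions /
    MS_error, p from the F distribution.  Post hoc: all k(k-1)/2 paired
    t-tests, Bonferroni correction min(1, p * n_pairs).

    Missing cells are rejected (no imputation).  MS_error = 0 is flagged
    degenerate: F = +inf, p = 0 if the condition effect is non-zero, else
    F = 0, p = 1.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2:
        raise StatsError("expected a 2-D subjects x conditions matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise StatsError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    if not np.all(np.isfinite(y)):
        raise StatsError("matrix contains missing or non-finite cells; no imputation is performed")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_subjects = k * float(np.sum((subj_means - grand) ** 2))
    ss_conditions = n * float(np.sum((cond_means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_error = ss_total - ss_subjects - ss_conditions

    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_conditions / df_effect
    # guard tiny negative rounding of ss_error
    ms_error = max(ss_error, 0.0) / df_error

    if ms_error == 0.0:
        if ms_cond == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
        degenerate = True
    else:
        f = ms_cond / ms_error
        p = float(sps.f.sf(f, df_effect, df_error))
        degenerate = False

    n_pairs = k * (k - 1) // 2
    posthoc: list[tuple[tuple[int, int], float, float]] = []
    for i, j in itertools.combinations(range(k), 2):
        diff = y[:, i] - y[:, j]
        if np.allclose(diff, diff[0]):
            # zero-variance differences: identical shift for every subject
            raw = 1.0 if diff[0] == 0 else 0.0
        else:
            raw = float(sps.ttest_rel(y[:, i], y[:, j]).pvalue)
        posthoc.append(((i, j), raw, min(1.0, raw * n_pairs)))

    return RmAnovaResult(
        f_stat=f,
        df_effect=df_effect,
        df_error=df_error,
        p_value=p,
        posthoc=posthoc,
        degenerate=degenerate,
    )


def between_visit_cv(visit_means: Sequence[float]) -> float:
    """Between-visit coefficient of variation, in percent.

    Defined over the k visit-level means (one mean per visit):
    100 * sd(visit means) / mean(visit means).  This is the visit-level
    repeatability of the cohort index, which is small even when the
    between-subject SEM is not.
    """
    m = np.asarray(visit_means, dtype=float)
    if m.size < 2:
        raise StatsError("between-visit CV needs >= 2 visit means")
    grand = float(np.mean(m))
    if grand == 0:
        raise StatsError("between-visit CV undefined: mean of visit means is 0")
    return 100.0 * float(np.std(m, ddof=1)) / abs(grand)
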