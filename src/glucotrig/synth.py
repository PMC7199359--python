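"""Synthetic postprandial cohort generator.

Emulates the healthy-adult crossover design the index was developed on:
each subject has latent fasting insulin / triglyceride / glucose levels
drawn from zero-truncated normals, each visit re-measures those levels
with small within-subject noise, and a mixed meal drives a multiplicative
insulin response and an additive triglyceride rise at 180 min.  Default
fasting moments match a healthy cohort (insulin 44.1 pmol/L, TG 0.8
mmol/L, glucose 4.4 mmol/L; between-subject sds reconstructed from
printed SEMs as sd = SEM * sqrt(10)).

The 180-min response parameters are calibration constants, not estimates:
no per-subject 180-min data are published, so the defaults are chosen to
give a reference-meal index of order 10^1 (analytic mean ~= 19, see
:func:`analytic_mean_index`).

Generation is two-time-point (0 and 180 min), matching the method; a
dense-trajectory mode exists for visualisation only and invents a smooth
curve family (insulin peaking at 30-60 min, TG still rising at 180 min)
that the two-point method never uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import MetabolicSample, VisitRecord

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "default_reference_config",
    "analytic_mean_index",
    "simulate_activity_profiles",
    "dense_trajectory",
    "SynthError",
]


class SynthError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Fasting means/sds are between-subject moments of the zero-truncated
    normal subject-level distributions (insulin pmol/L, TG and glucose
    mmol/L).  ``*_visit_sd`` are within-subject re-measurement sds.
    ``insulin_fold_180`` multiplies fasting insulin at 180 min (with
    unit-mean lognormal noise of sigma ``insulin_response_sigma``);
    ``tg_rise_180`` adds to fasting TG at 180 min (with Gaussian noise sd
    ``tg_response_sd``, floored at 0).  Glucose is a side outcome:
    ``glucose_change_180`` defaults to 0 (returned to baseline).
    """

    n_subjects: int = 10
    n_visits: int = 3
    seed: int = 0

    insulin_fasting_mean: float = 44.1
    insulin_fasting_sd: float = 13.914        # 4.4 SEM * sqrt(10)
    tg_fasting_mean: float = 0.8
    tg_fasting_sd: float = 0.3162             # 0.1 SEM * sqrt(10)
    glucose_fasting_mean: float = 4.4
    glucose_fasting_sd: float = 0.4427        # 0.14 SEM * sqrt(10)

    insulin_visit_sd: float = 3.0
    tg_visit_sd: float = 0.05
    glucose_visit_sd: float = 0.1

    insulin_fold_180: float = 1.3
    insulin_response_sigma: float = 0.2
    tg_rise_180: float = 0.15
    tg_response_sd: float = 0.1
    glucose_change_180: float = 0.0
    glucose_response_sd: float = 0.3

    postprandial_time_min: int = 180
    meal_label: str = "reference meal"

    def __post_init__(self) -> None:
        if not (isinstance(self.n_subjects, int) and self.n_subjects >= 1):
            raise SynthError(f"n_subjects must be a positive integer, got {self.n_subjects!r}")
        if not (isinstance(self.n_visits, int) and self.n_visits >= 1):
            raise SynthError(f"n_visits must be a positive integer, got {self.n_visits!r}")
        for name in (
            "insulin_fasting_mean", "tg_fasting_mean", "glucose_fasting_mean",
            "insulin_fold_180",
        ):
            if getattr(self, name) <= 0:
                raise SynthError(f"{name} must be > 0")
        for name in (
            "insulin_fasting_sd", "tg_fasting_sd", "glucose_fasting_sd",
            "insulin_visit_sd", "tg_visit_sd", "glucose_visit_sd",
            "insulin_response_sigma", "tg_response_sd", "glucose_response_sd",
        ):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")
        if self.postprandial_time_min <= 0:
            raise SynthError("postprandial_time_min must be > 0")


def default_reference_config(seed: int = 0) -> SimulationConfig:
    """The documented default calibration: a 10-subject, 3-visit
    reference-meal cohort with healthy-adult fasting moments."""
    return SimulationConfig(seed=seed)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Zero-truncated normal draws (exact truncation, not clipping)."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _trunc_normal_mean(mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd
    return float(sps.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def simulate_cohort(config: SimulationConfig) -> list[VisitRecord]:
    """Draw a full synthetic cohort: n_subjects x n_visits VisitRecords.

    Deterministic for a fixed config (the seed lives in the config); all
    generated concentrations are >= 0.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_subjects, config.n_visits

    subj_ins = _trunc_normal(rng, config.insulin_fasting_mean, config.insulin_fasting_sd, n)
    subj_tg = _trunc_normal(rng, config.tg_fasting_mean, config.tg_fasting_sd, n)
    subj_glu = _trunc_normal(rng, config.glucose_fasting_mean, config.glucose_fasting_sd, n)

    records: list[VisitRecord] = []
    for s in range(n):
        sid = f"S{s + 1:03d}"
        for v in range(1, k + 1):
            ins0 = max(subj_ins[s] + rng.normal(0.0, config.insulin_visit_sd), 0.0)
            tg0 = max(subj_tg[s] + rng.normal(0.0, config.tg_visit_sd), 0.0)
            glu0 = max(subj_glu[s] + rng.normal(0.0, config.glucose_visit_sd), 0.0)

            # unit-mean lognormal multiplicative response noise
            sig = config.insulin_response_sigma
            ln_noise = math.exp(rng.normal(-0.5 * sig * sig, sig)) if sig > 0 else 1.0
            ins180 = ins0 * config.insulin_fold_180 * ln_noise
            tg180 = max(
                tg0 + config.tg_rise_180 + rng.normal(0.0, config.tg_response_sd)
                if config.tg_response_sd > 0
                else tg0 + config.tg_rise_180,
                0.0,
            )
            glu180 = max(
                glu0 + config.glucose_change_180 + rng.normal(0.0, config.glucose_response_sd)
                if config.glucose_response_sd > 0
                else glu0 + config.glucose_change_180,
                0.0,
            )

            records.append(
                VisitRecord(
                    subject_id=sid,
                    visit=v,
                    meal_label=config.meal_label,
                    baseline=MetabolicSample(0, insulin=ins0, triglycerides=tg0, glucose=glu0),
                    postprandial=MetabolicSample(
                        config.postprandial_time_min,
                        insulin=ins180,
                        triglycerides=tg180,
                        glucose=glu180,
                    ),
                )
            )
    return records


def analytic_mean_index(config: SimulationConfig) -> float:
    """Closed-form expected GlucoTRIG value under the generator.

    With mu_I, mu_T the (zero-truncated) subject-level fasting means, f
    the insulin fold and r the TG rise, and all noise terms independent
    with mean zero (additive) or mean one (multiplicative):

        E[TG180*INS180] - E[TG0*INS0] = mu_T*mu_I*(f - 1) + f*r*mu_I

    The small flooring of noisy visit values at 0 is neglected (default
    sds put 0 several sigma below every mean).
    """
    mu_i = _trunc_normal_mean(config.insulin_fasting_mean, config.insulin_fasting_sd)
    mu_t = _trunc_normal_mean(config.tg_fasting_mean, config.tg_fasting_sd)
    f, r = config.insulin_fold_180, config.tg_rise_180
    return mu_t * mu_i * (f - 1.0) + f * r * mu_i


def simulate_activity_profiles(
    n_low: int, n_moderate: int, n_high: int, seed: int = 0
):
    """Synthetic weekly activity profiles per target category (e.g. the
    7 low / 3 moderate split of a sedentary healthy cohort).

    Each profile is drawn from a parameter region that scores to its
    target category, so classification round-trips by construction.
    Returns a list of (ActivityProfile, category) in low, moderate, high
    order.
    """
    from .ipaq import ActivityProfile

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_low):
        # a little light walking; below every moderate clause
        out.append(
            (
                ActivityProfile(
                    walking_days=int(rng.integers(0, 5)),
                    walking_min_per_day=float(rng.uniform(5, 25)),
                ),
                "low",
            )
        )
    for _ in range(n_moderate):
        # 5-7 walking days of >= 30 min, well under the high thresholds
        out.append(
            (
                ActivityProfile(
                    walking_days=int(rng.integers(5, 8)),
                    walking_min_per_day=float(rng.uniform(30, 60)),
                ),
                "moderate",
            )
        )
    for _ in range(n_high):
        # >= 3 vigorous days, comfortably past 1500 MET-min/week
        out.append(
            (
                ActivityProfile(
                    vigorous_days=int(rng.integers(3, 8)),
                    vigorous_min_per_day=float(rng.uniform(60, 90)),
                ),
                "high",
            )
        )
    return out


def dense_trajectory(
    config: SimulationConfig,
    times_min: Sequence[int] = (0, 30, 60, 90, 120, 180, 240),
    seed: int | None = None,
):
    """Illustrative dense postprandial curves (visualisation only).

    Produces population-mean insulin and TG trajectories with the
    qualitative shape of a mixed-meal response: insulin peaks at 30-60
    min and decays back toward fasting, TG climbs monotonically through
    180 min and peaks near 180-240 min.  The curve family (gamma-shaped
    insulin excursion, saturating TG rise) is an invention for plotting;
    the index itself only ever uses the 0 and 180 min draws.

    Returns a dict with keys ``time_min``, ``insulin``, ``triglycerides``.
    """
    t = np.asarray(times_min, dtype=float)
    mu_i = config.insulin_fasting_mean
    mu_t = config.tg_fasting_mean

    # gamma-shaped insulin excursion, peak at 45 min, tuned so the 180-min
    # level equals fasting * insulin_fold_180
    peak_t = 45.0
    shape = (t / peak_t) * np.exp(1.0 - t / peak_t)
    level_180 = (180.0 / peak_t) * math.exp(1.0 - 180.0 / peak_t)
    excess_180 = config.insulin_fold_180 - 1.0
    amp = excess_180 / level_180 if level_180 > 0 else 0.0
    insulin = mu_i * (1.0 + amp * shape)

    # TG: saturating rise, still increasing at 180 min, peak ~210 min
    rise = config.tg_rise_180 * np.where(
        t <= 210.0,
        np.sin(np.clip(t / 210.0, 0, 1) * math.pi / 2) / math.sin(math.pi / 2 * 180.0 / 210.0),
        np.sin(math.pi / 2) / math.sin(math.pi / 2 * 180.0 / 210.0) * (1.0 - 0.05 * (t - 210.0) / 30.0),
    )
    tg = mu_t + rise
    return {"time_min": t.tolist(), "insulin": insulin.tolist(), "triglycerides": tg.tolist()}
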