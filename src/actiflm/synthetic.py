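"""Synthetic crossover actigraphy trials.

Generates cohorts of arthritic dogs, a two-period crossover calendar,
minute-epoch activity counts with circadian structure, owner sleep diaries,
and questionnaire responses.  The activity model is a two-harmonic cosinor
on the log scale driving an overdispersed (negative-binomial-type) count
law, with a weekend uplift, a per-subject random intercept, and treatment
effects that multiply the mean inside configurable clock-time windows under
the drug condition only.

Clock-time windows live on a circular 1440-minute clock: a window whose
start exceeds its end wraps across midnight (e.g. ``(1380, 360)`` is
23:00-06:00).  Minutes before noon are attributed to the previous calendar
day's condition ("circadian day" anchored on the evening dose), so a night
window spanning midnight sits wholly inside one condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import stats

from .design import TrialDesign
from .io import EpochSeries

MINUTES_PER_DAY = 1440

__all__ = [
    "CohortSpec",
    "ActivityModel",
    "SnoreEffectSpec",
    "SpecValidationError",
    "simulate_cohort",
    "simulate_activity",
    "simulate_snore",
    "window_mask",
]


class SpecValidationError(ValueError):
    """A simulation specification field is invalid (message names the field)."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{field_name}: {msg}")


# ----------------------------------------------------------------------
# Cohort
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CohortSpec:
    """Population parameters for the simulated cohort.

    Defaults reproduce the study population this pipeline is modelled on:
    15 osteoarthritic dogs (10 female / 5 male), age 10.29 +/- 2.48 years,
    weight 31.53 +/- 5.39 kg, baseline CBPI pain sub-score 3.85 +/- 1.5.
    """

    n_subjects: int = 15
    age_mean: float = 10.29
    age_sd: float = 2.48
    weight_mean: float = 31.53
    weight_sd: float = 5.39
    cbpi_mean: float = 3.85
    cbpi_sd: float = 1.5
    n_female: int = 10
    n_male: int = 5

    def __post_init__(self) -> None:
        _require(self.n_subjects >= 2, "n_subjects", "must be >= 2")
        for f in ("age_sd", "weight_sd", "cbpi_sd"):
            _require(getattr(self, f) >= 0, f, "must be >= 0")
        _require(self.n_female >= 0, "n_female", "must be >= 0")
        _require(self.n_male >= 0, "n_male", "must be >= 0")
        _require(
            self.n_female + self.n_male == self.n_subjects,
            "n_female",
            f"n_female + n_male must equal n_subjects "
            f"({self.n_female}+{self.n_male} != {self.n_subjects})",
        )


def simulate_cohort(spec: CohortSpec, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a subject covariate table from a :class:`CohortSpec`.

    Returns a frame with columns ``subject_id, age, weight, sex, cbpi``.
    Ages and weights are normal draws floored at small positive values;
    CBPI is clipped to the 0-10 instrument range.  Reproducible for a
    fixed integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subjects
    ids = [f"d{i + 1:02d}" for i in range(n)]
    age = np.maximum(rng.normal(spec.age_mean, spec.age_sd, n), 0.1)
    weight = np.maximum(rng.normal(spec.weight_mean, spec.weight_sd, n), 0.5)
    cbpi = np.clip(rng.normal(spec.cbpi_mean, spec.cbpi_sd, n), 0.0, 10.0)
    sex = np.array(["F"] * spec.n_female + ["M"] * spec.n_male, dtype=object)
    rng.shuffle(sex)
    return pd.DataFrame(
        {"subject_id": ids, "age": age, "weight": weight, "sex": sex, "cbpi": cbpi}
    )


# ----------------------------------------------------------------------
# Activity
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ActivityModel:
    """Generative model for minute-epoch activity counts.

    The log mean intensity at clock minute *t* is::

        intercept + sum_h  amp_h * cos(2*pi*(t - phase_h)/period_h)
                  + b_subject
                  + log(weekend_multiplier) * [weekend day]
                  + log(m_w)                * [drug condition and t in window w]

    Counts are drawn from a gamma-Poisson mixture with variance-to-mean
    ratio ``dispersion`` (1 = Poisson; default 3, i.e. variance = 3x mean,
    matching the overdispersion typical of accelerometer counts).

    ``harmonics`` is a tuple of ``(amplitude, phase_minute, period_minute)``
    triples; the defaults give a mid-afternoon activity peak (~14:00), a
    deep night trough (~02:00) and a shallow midday lull.

    ``effect_windows`` is a tuple of ``(start_minute, end_minute,
    multiplier)``; defaults emulate an analgesic that reduces night
    activity 23:00-06:00 (x0.5) and raises morning activity 07:00-12:00
    (x1.3).  Use :meth:`null` for a no-effect model.
    """

    intercept: float = math.log(30.0)
    harmonics: tuple[tuple[float, float, float], ...] = (
        (1.4, 840.0, 1440.0),
        (0.4, 480.0, 720.0),
    )
    subject_sd: float = 0.3
    weekend_multiplier: float = 1.15
    dispersion: float = 3.0
    effect_windows: tuple[tuple[float, float, float], ...] = (
        (1380.0, 360.0, 0.5),
        (420.0, 720.0, 1.3),
    )
    bed_mean: float = 1380.0  # 23:00, clock minutes
    bed_sd: float = 30.0
    rise_mean: float = 390.0  # 06:30
    rise_sd: float = 30.0
    diary_truncation: float = 120.0  # +/- bound on diary-time deviations, minutes
    evening_ramp: bool = False  # ramp drug multipliers toward 1 before the dose
    dose_minute: float = 1080.0  # 18:00

    def __post_init__(self) -> None:
        _require(self.subject_sd >= 0, "subject_sd", "must be >= 0")
        _require(self.weekend_multiplier > 0, "weekend_multiplier", "must be > 0")
        _require(self.dispersion >= 1.0, "dispersion", "variance/mean ratio must be >= 1")
        _require(self.bed_sd >= 0, "bed_sd", "must be >= 0")
        _require(self.rise_sd >= 0, "rise_sd", "must be >= 0")
        _require(self.diary_truncation > 0, "diary_truncation", "must be > 0")
        arcs: list[tuple[float, float]] = []
        for w in self.effect_windows:
            if len(w) != 3:
                raise SpecValidationError(
                    "effect_windows: each window must be (start, end, multiplier)"
                )
            start, end, mult = w
            _require(mult > 0, "effect_windows", f"multiplier must be > 0, got {mult}")
            _require(0 <= start < MINUTES_PER_DAY, "effect_windows",
                     f"start {start} outside [0, 1440)")
            _require(0 < end <= MINUTES_PER_DAY, "effect_windows",
                     f"end {end} outside (0, 1440]")
            _require(start != end, "effect_windows", "zero-length window")
            if start < end:  # plain arc
                arcs.append((start, end))
            else:  # wraps midnight: two arcs
                arcs.append((start, MINUTES_PER_DAY))
                arcs.append((0.0, end))
        arcs.sort()
        for (s1, e1), (s2, e2) in zip(arcs, arcs[1:]):
            _require(e1 <= s2, "effect_windows",
                     f"windows overlap on the circular clock near minute {s2:.0f}")

    def null(self) -> "ActivityModel":
        """Copy of this model with all treatment-effect windows removed."""
        return replace(self, effect_windows=())

    def log_mean_clock(self, clock_minutes: np.ndarray) -> np.ndarray:
        """Baseline log mean intensity as a function of clock minute."""
        t = np.asarray(clock_minutes, dtype=float)
        out = np.full(t.shape, self.intercept)
        for amp, phase, period in self.harmonics:
            out += amp * np.cos(2 * np.pi * (t - phase) / period)
        return out


def window_mask(clock_minutes: np.ndarray, start: float, end: float) -> np.ndarray:
    """Boolean membership of clock minutes in a (possibly wrapping) window."""
    t = np.asarray(clock_minutes)
    if start < end:
        return (t >= start) & (t < end)
    return (t >= start) | (t < end)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bound: float, size: int
) -> np.ndarray:
    """Normal draws truncated to mean +/- bound."""
    if sd == 0:
        return np.full(size, mean)
    a, b = -bound / sd, bound / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _overdispersed_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Counts with E=mu, Var=dispersion*mu via a gamma-Poisson mixture."""
    if dispersion <= 1.0 + 1e-12:
        return rng.poisson(mu)
    scale = dispersion - 1.0
    lam = rng.gamma(shape=mu / scale, scale=scale)
    return rng.poisson(lam)


def simulate_activity(
    cohort: pd.DataFrame,
    design: TrialDesign,
    model: ActivityModel,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, EpochSeries], pd.DataFrame]:
    """Simulate minute-epoch activity and sleep diaries for a whole trial.

    Returns
    -------
    series : dict of subject_id -> EpochSeries
        One count per minute from trial day 1, 00:00 to the last trial
        day, 24:00.
    diary : DataFrame
        One row per subject-night: ``subject_id, date, bed_time,
        rise_time`` where ``date`` is the night's evening-onset date.
        Nights are generated from the eve of day 1 through the last trial
        day so every simulated minute is covered.
    """
    if cohort.empty:
        raise SpecValidationError("cohort: must contain at least one subject")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_days = design.n_days
    n_min = n_days * MINUTES_PER_DAY

    minute = np.arange(n_min)
    clock = minute % MINUTES_PER_DAY
    day = minute // MINUTES_PER_DAY + 1  # 1-based trial day of the calendar date
    # condition attribution: minutes before noon belong to the previous day
    anchor_day = np.where(clock >= MINUTES_PER_DAY // 2, day, day - 1)

    start = pd.Timestamp(design.start_date)
    index = pd.date_range(start, periods=n_min, freq="min")
    date_weekday = np.array(
        [(design.start_date + pd.Timedelta(days=d)).weekday() for d in range(n_days)]
    )
    is_weekend_min = (date_weekday[day - 1] >= 5)

    base_log_mu = model.log_mean_clock(clock) + np.log(model.weekend_multiplier) * is_weekend_min

    # per-window in-clock masks, shared across subjects
    win_masks = [
        (window_mask(clock, s, e), math.log(m)) for s, e, m in model.effect_windows
    ]
    if model.evening_ramp:
        ramp = np.clip((model.dose_minute - clock) % MINUTES_PER_DAY, 0, 60) / 60.0
        # within the hour before dosing the log-effect decays linearly to 0
        ramp_factor = np.where(window_mask(clock, model.dose_minute - 60, model.dose_minute),
                               1.0 - ramp, 1.0)
    else:
        ramp_factor = None

    series: dict[str, EpochSeries] = {}
    diary_rows = []
    night_days = np.arange(0, n_days + 1)  # onset day 0 = eve of day 1

    for sid in cohort["subject_id"]:
        b_subj = rng.normal(0.0, model.subject_sd)
        cond_by_day = design.condition_codes(sid, max_day=n_days)
        is_drug = cond_by_day[anchor_day] == "drug"
        log_mu = base_log_mu + b_subj
        for mask, log_m in win_masks:
            eff = np.where(is_drug & mask, log_m, 0.0)
            if ramp_factor is not None:
                eff = eff * ramp_factor
            log_mu = log_mu + eff
        counts = _overdispersed_counts(rng, np.exp(log_mu), model.dispersion)
        series[sid] = EpochSeries(
            subject_id=str(sid), counts=pd.Series(counts, index=index, name="count")
        )

        beds = _truncated_normal(
            rng, model.bed_mean, model.bed_sd, model.diary_truncation, len(night_days)
        )
        # keep the evening-onset diary convention exact: a bed time drawn past
        # midnight is recorded as 23:59 on the onset date
        beds = np.minimum(beds, MINUTES_PER_DAY - 1)
        rises = _truncated_normal(
            rng, model.rise_mean, model.rise_sd, model.diary_truncation, len(night_days)
        )
        for d, bed, rise in zip(night_days, beds, rises):
            onset = design.date_of_day(int(d))
            diary_rows.append(
                {
                    "subject_id": str(sid),
                    "date": onset,
                    "bed_time": _fmt_clock(bed),
                    "rise_time": _fmt_clock(rise),
                }
            )

    diary = pd.DataFrame(diary_rows)
    return series, diary


def _fmt_clock(minutes: float) -> str:
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


# ----------------------------------------------------------------------
# Questionnaire
# ----------------------------------------------------------------------
N_ITEMS = 6


def snore_schedule(design: TrialDesign) -> tuple[int, ...]:
    """Assessment days: baseline, end of period 1, end of washout,
    mid period 2, end of period 2 (0/14/21/28/35 under the default design)."""
    p1 = design.period_length
    w_end = p1 + design.washout_length
    return tuple(sorted({0, p1, w_end, w_end + design.period_length // 2,
                         design.n_days}))


@dataclass(frozen=True)
class SnoreEffectSpec:
    """Generative model for 6-item sleep-quality questionnaire scores.

    A subject's score on item *i* at an assessment is::

        baseline_i + u_subject,i + shift_i(condition) + noise

    where ``corr`` splits the item variance between the stable
    subject-level component ``u`` and assessment-level noise.  Scores are
    clamped to ``scale`` (a continuous 0-10 response by default; set
    ``integer_scores`` for a rounded integer scale).  Default shifts
    reproduce the pattern of a trial in which the drug most improved
    twitching and dreaming (items 2-3) while item 6 (pacing) was
    unresponsive.
    """

    item_means: tuple[float, ...] = (5.0, 4.5, 5.0, 4.0, 3.5, 2.0)
    item_sds: tuple[float, ...] = (1.5,) * N_ITEMS
    drug_shifts: tuple[float, ...] = (-1.00, -1.20, -1.80, -1.13, -1.07, 0.27)
    placebo_shifts: tuple[float, ...] = (-0.33, -0.20, -0.40, -0.13, -0.60, 0.33)
    corr: float = 0.5
    scale: tuple[float, float] = (0.0, 10.0)
    integer_scores: bool = False

    def __post_init__(self) -> None:
        for f in ("item_means", "item_sds", "drug_shifts", "placebo_shifts"):
            _require(len(getattr(self, f)) == N_ITEMS, f, f"must have {N_ITEMS} entries")
        _require(all(s >= 0 for s in self.item_sds), "item_sds", "must be >= 0")
        _require(0.0 <= self.corr <= 1.0, "corr", "must lie in [0, 1]")
        _require(self.scale[0] < self.scale[1], "scale", "low bound must be < high bound")


def simulate_snore(
    cohort: pd.DataFrame,
    design: TrialDesign,
    effects: SnoreEffectSpec,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate questionnaire responses on the day-0/14/21/28/35 schedule.

    Day 0 is pre-treatment baseline; days 14 and 35 close periods 1 and 2
    and carry that period's condition shift; day 28 (mid period 2) carries
    the period-2 shift; day 21 (washout) carries none.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(effects.item_means)
    sd = np.asarray(effects.item_sds)
    sd_between = np.sqrt(effects.corr) * sd
    sd_within = np.sqrt(1.0 - effects.corr) * sd
    p1_end = design.period_length
    washout_end = p1_end + design.washout_length

    rows = []
    schedule = snore_schedule(design)
    for sid in cohort["subject_id"]:
        u = rng.normal(0.0, sd_between)
        first, second = design.sequence[str(sid)]
        for dday in schedule:
            if dday == 0 or p1_end < dday <= washout_end:
                shift = np.zeros(N_ITEMS)  # baseline or washout assessment
            elif dday <= p1_end:
                shift = np.asarray(
                    effects.drug_shifts if first == "drug" else effects.placebo_shifts
                )
            else:
                shift = np.asarray(
                    effects.drug_shifts if second == "drug" else effects.placebo_shifts
                )
            score = mu + u + shift + rng.normal(0.0, sd_within)
            score = np.clip(score, *effects.scale)
            if effects.integer_scores:
                score = np.round(score)
            rows.append(
                {"subject_id": str(sid), "day": dday,
                 **{f"q{i + 1}": score[i] for i in range(N_ITEMS)}}
            )
    return pd.DataFrame(rows)
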