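"""Tabular IO, diary-based night/day classification, and daily profiles.

File dialects (all plain CSV, naive local timestamps):

* activity:   ``subject_id,timestamp,count`` — one row per minute epoch,
  ISO-8601 timestamps, nonnegative integer counts.
* diary:      ``subject_id,date,bed_time,rise_time`` — one row per night,
  ``date`` is the evening-onset date, times are ``HH:MM``.
* covariates: ``subject_id,age,weight,sex,cbpi`` — sex in {F, M}.
* snore:      ``subject_id,day,q1..q6`` — day in {0, 14, 21, 28, 35}.

Epochs are classified as night-time activity (NTA) while the clock lies in
the owner-reported ``[bed_time, rise_time)`` window of that night (half-open
on the circular clock) and day-time activity (DTA) otherwise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import TrialDesign

MINUTES_PER_DAY = 1440

#: Fixed fallback night window (00:00-05:00) used when a diary night is
#: missing: the designated night-time of the precursor summary analysis.
DEFAULT_NIGHT_WINDOW = (0, 300)

__all__ = [
    "EpochSeries",
    "SleepDiary",
    "LabeledEpochs",
    "DailyProfile",
    "ParseError",
    "read_activity",
    "write_activity",
    "read_diary",
    "write_diary",
    "read_covariates",
    "write_covariates",
    "read_snore",
    "write_snore",
    "classify_epochs",
    "build_daily_profiles",
    "rebin_profile",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


# ----------------------------------------------------------------------
# Containers
# ----------------------------------------------------------------------
@dataclass
class EpochSeries:
    """Minute-stamped activity counts for one subject.

    ``counts`` is a pandas Series with a strictly increasing
    DatetimeIndex at 1-minute spacing within each day (gaps allowed
    between days) and nonnegative integer values.
    """

    subject_id: str
    counts: pd.Series

    def __post_init__(self) -> None:
        idx = self.counts.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("EpochSeries requires a DatetimeIndex")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError(f"{self.subject_id}: timestamps not increasing")

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EpochSeries)
            and self.subject_id == other.subject_id
            and self.counts.equals(other.counts)
        )


@dataclass
class SleepDiary:
    """Owner-reported bed and rise times for one subject.

    ``nights`` has one row per night: columns ``date`` (evening-onset
    date), ``bed_minute`` and ``rise_minute`` (clock minutes).  A night
    wraps past midnight when ``rise_minute <= bed_minute``; otherwise bed
    and rise fall on the onset date itself (an afternoon nap diary).
    """

    subject_id: str
    nights: pd.DataFrame

    def night_bounds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Absolute night intervals as (onset_date, start_ts, end_ts) arrays."""
        dates = pd.to_datetime(self.nights["date"]).to_numpy()
        bed = self.nights["bed_minute"].to_numpy(float)
        rise = self.nights["rise_minute"].to_numpy(float)
        start = dates + bed.astype("timedelta64[m]")
        wrap = rise <= bed
        end = dates + (rise + np.where(wrap, MINUTES_PER_DAY, 0)).astype("timedelta64[m]")
        return dates, start, end


@dataclass
class LabeledEpochs:
    """An EpochSeries with per-epoch NTA/DTA label, condition and flags.

    ``frame`` columns: ``timestamp, count, label`` (``"NTA"``/``"DTA"``),
    ``condition`` (drug/placebo/washout/baseline), ``weekend`` (bool) and
    ``attr_date`` — the date a row is attributed to: the night's onset
    date for NTA epochs, the calendar date for DTA epochs.
    """

    subject_id: str
    frame: pd.DataFrame


@dataclass
class DailyProfile:
    """A 24-hour activity profile on a fixed clock grid.

    ``values[i]`` is the mean count/min over clock minutes
    ``[i*1440/G, (i+1)*1440/G)``; cells with no covered minutes are NaN.
    """

    subject_id: str
    condition: str
    values: np.ndarray
    n_days: int
    date: dt.date | None = None  # set for per-day profiles

    @property
    def grid_size(self) -> int:
        return len(self.values)

    @property
    def coverage(self) -> float:
        """Fraction of grid cells with at least one observed minute."""
        return float(np.mean(~np.isnan(self.values)))


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------
def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def read_activity(path: str | Path) -> dict[str, EpochSeries]:
    """Read an activity CSV into per-subject :class:`EpochSeries`.

    Rejects non-monotone timestamps, duplicate (subject, timestamp) pairs
    and negative or non-integer counts, reporting 1-based file line
    numbers (header = line 1).
    """
    df = _read_csv(path, ["subject_id", "timestamp", "count"])
    lines = df.index.to_numpy() + 2  # header occupies line 1
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = ts.isna().to_numpy()
    if bad.any():
        raise ParseError(f"{path}: unparseable timestamp at line {lines[bad][0]}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna().to_numpy() | (counts.to_numpy(float) % 1 != 0)
    if bad.any():
        raise ParseError(f"{path}: non-integer count at line {lines[bad][0]}")
    if (counts < 0).any():
        raise ParseError(
            f"{path}: negative count at line {lines[(counts < 0).to_numpy()][0]}"
        )
    out: dict[str, EpochSeries] = {}
    for sid, grp in df.assign(_ts=ts, _n=counts.astype(np.int64)).groupby(
        "subject_id", sort=True
    ):
        tvals = grp["_ts"].to_numpy()
        glines = grp.index.to_numpy() + 2
        diffs = np.diff(tvals).astype("timedelta64[s]").astype(np.int64)
        if (diffs == 0).any():
            raise ParseError(
                f"{path}: duplicate timestamp for subject {sid} at line "
                f"{glines[1:][diffs == 0][0]}"
            )
        if (diffs < 0).any():
            raise ParseError(
                f"{path}: non-monotone timestamp for subject {sid} at line "
                f"{glines[1:][diffs < 0][0]}"
            )
        same_day = tvals[1:].astype("datetime64[D]") == tvals[:-1].astype("datetime64[D]")
        if (same_day & (diffs != 60)).any():
            raise ParseError(
                f"{path}: non-1-minute spacing for subject {sid} at line "
                f"{glines[1:][same_day & (diffs != 60)][0]}"
            )
        out[str(sid)] = EpochSeries(
            subject_id=str(sid),
            counts=pd.Series(
                grp["_n"].to_numpy(), index=pd.DatetimeIndex(tvals), name="count"
            ),
        )
    return out


def write_activity(series: Mapping[str, EpochSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "timestamp": s.counts.index.strftime("%Y-%m-%dT%H:%M:%S"),
                "count": s.counts.to_numpy(),
            }
        )
        for _, s in sorted(series.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _parse_clock(val: str, path, line: int, col: str) -> int:
    try:
        h, m = str(val).split(":")
        h, m = int(h), int(m)
        if not (0 <= h < 24 and 0 <= m < 60):
            raise ValueError
    except ValueError:
        raise ParseError(f"{path}: bad {col} {val!r} at line {line}") from None
    return h * 60 + m


def read_diary(path: str | Path) -> dict[str, SleepDiary]:
    """Read a sleep-diary CSV into per-subject :class:`SleepDiary`."""
    df = _read_csv(path, ["subject_id", "date", "bed_time", "rise_time"])
    rows = []
    for i, r in df.iterrows():
        line = i + 2
        try:
            date = dt.date.fromisoformat(str(r["date"]))
        except ValueError:
            raise ParseError(f"{path}: bad date {r['date']!r} at line {line}") from None
        bed = _parse_clock(r["bed_time"], path, line, "bed_time")
        rise = _parse_clock(r["rise_time"], path, line, "rise_time")
        if bed == rise:
            raise ParseError(f"{path}: zero-length night at line {line}")
        rows.append(
            {"subject_id": str(r["subject_id"]), "date": date,
             "bed_minute": bed, "rise_minute": rise}
        )
    full = pd.DataFrame(rows)
    out = {}
    for sid, grp in full.groupby("subject_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if grp["date"].duplicated().any():
            d = grp.loc[grp["date"].duplicated(), "date"].iloc[0]
            raise ParseError(f"{path}: duplicate diary night {d} for subject {sid}")
        out[str(sid)] = SleepDiary(subject_id=str(sid), nights=grp)
    return out


def diary_from_frame(diary: pd.DataFrame) -> dict[str, SleepDiary]:
    """Build SleepDiary objects from a frame with HH:MM time columns."""
    rows = []
    for _, r in diary.iterrows():
        rows.append(
            {
                "subject_id": str(r["subject_id"]),
                "date": r["date"] if isinstance(r["date"], dt.date) else
                dt.date.fromisoformat(str(r["date"])),
                "bed_minute": _parse_clock(r["bed_time"], "<frame>", -1, "bed_time"),
                "rise_minute": _parse_clock(r["rise_time"], "<frame>", -1, "rise_time"),
            }
        )
    full = pd.DataFrame(rows)
    return {
        str(sid): SleepDiary(
            subject_id=str(sid), nights=grp.sort_values("date").reset_index(drop=True)
        )
        for sid, grp in full.groupby("subject_id", sort=True)
    }


def write_diary(diary: pd.DataFrame, path: str | Path) -> None:
    out = diary.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat() if hasattr(d, "isoformat") else d)
    out.to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the subject covariate CSV (age, weight, sex, CBPI)."""
    df = _read_csv(path, ["subject_id", "age", "weight", "sex", "cbpi"])
    sex = df["sex"].astype(str).str.upper()
    bad = ~sex.isin(["F", "M"])
    if bad.any():
        raise ParseError(
            f"{path}: unknown sex code {df['sex'][bad].iloc[0]!r} at line "
            f"{df.index[bad][0] + 2}"
        )
    df = df.copy()
    df["sex"] = sex
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("age", "weight", "cbpi"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(
                f"{path}: non-numeric {col} at line {df.index[vals.isna()][0] + 2}"
            )
        df[col] = vals
    return df


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, index=False)


def read_snore(path: str | Path) -> pd.DataFrame:
    """Read the questionnaire CSV (one row per subject-assessment)."""
    cols = ["subject_id", "day"] + [f"q{i}" for i in range(1, 7)]
    df = _read_csv(path, cols)
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["day"] = pd.to_numeric(df["day"], errors="coerce")
    bad = df["day"].isna() | (df["day"] < 0) | (df["day"] % 1 != 0)
    if bad.any():
        raise ParseError(
            f"{path}: invalid assessment day at line {df.index[bad][0] + 2}"
        )
    df["day"] = df["day"].astype(int)
    return df


def write_snore(snore: pd.DataFrame, path: str | Path) -> None:
    snore.to_csv(path, index=False)


# ----------------------------------------------------------------------
# Classification
# ----------------------------------------------------------------------
def classify_epochs(
    series: EpochSeries,
    diary: SleepDiary | None,
    design: TrialDesign,
    fallback_window: tuple[int, int] = DEFAULT_NIGHT_WINDOW,
) -> LabeledEpochs:
    """Label every epoch NTA or DTA and attach condition and weekend flags.

    An epoch is NTA iff it falls in some night's half-open
    ``[bed, rise)`` window.  Nights missing from the diary (or a ``None``
    diary) use ``fallback_window`` as fixed clock bounds.  NTA epochs take
    their condition and weekend flag from the night's evening-onset date
    (a Friday- or Saturday-onset night is a weekend night); DTA epochs
    from the calendar date (Saturday/Sunday = weekend).

    Raises if the series extends past the end of the trial span.
    """
    ts = series.counts.index.to_numpy()
    n = len(ts)
    if n == 0:
        raise ValueError(f"{series.subject_id}: empty series")
    t0 = np.datetime64(design.start_date)
    abs_min = (ts - t0).astype("timedelta64[m]").astype(np.int64)
    day = abs_min // MINUTES_PER_DAY + 1  # 1-based trial day of the calendar date
    if day.max() > design.n_days:
        raise ValueError(
            f"{series.subject_id}: series extends to trial day {day.max()}, "
            f"outside the {design.n_days}-day design span"
        )

    # build per-night absolute [start, end) bounds covering the series span
    first_onset = int(day.min()) - 1
    last_onset = int(day.max())
    onset_days = np.arange(first_onset, last_onset + 1)
    by_date = {}
    if diary is not None:
        for _, r in diary.nights.iterrows():
            by_date[pd.Timestamp(r["date"]).date()] = (
                int(r["bed_minute"]), int(r["rise_minute"])
            )
    fb_bed, fb_rise = fallback_window
    starts = np.empty(len(onset_days), dtype=np.int64)
    ends = np.empty(len(onset_days), dtype=np.int64)
    for i, d in enumerate(onset_days):
        onset_date = design.date_of_day(int(d))
        bed, rise = by_date.get(onset_date, (fb_bed, fb_rise))
        base = (int(d) - 1) * MINUTES_PER_DAY  # abs minute of onset date 00:00
        starts[i] = base + bed
        ends[i] = base + rise + (MINUTES_PER_DAY if rise <= bed else 0)
    if (starts[1:] < ends[:-1]).any():
        raise ValueError(f"{series.subject_id}: diary nights overlap")

    idx = np.searchsorted(starts, abs_min, side="right") - 1
    idx_c = np.clip(idx, 0, len(starts) - 1)
    is_nta = (idx >= 0) & (abs_min < ends[idx_c])
    night_onset_day = onset_days[idx_c]

    attr_day = np.where(is_nta, night_onset_day, day)
    weekday = np.array(
        [
            (design.start_date + dt.timedelta(days=int(d))).weekday()
            for d in range(int(attr_day.min()) - 1, int(attr_day.max()))
        ]
    )
    attr_weekday = weekday[attr_day - int(attr_day.min())]
    # NTA weekend: onset Friday(4)/Saturday(5); DTA weekend: Sat(5)/Sun(6)
    weekend = np.where(is_nta, (attr_weekday == 4) | (attr_weekday == 5),
                       (attr_weekday == 5) | (attr_weekday == 6))

    max_day = int(attr_day.max())
    cond_by_day = design.condition_codes(series.subject_id, max_day=max_day)
    cond_categories = ["baseline", "drug", "placebo", "washout"]
    code_of = {c: i for i, c in enumerate(cond_categories)}
    day_codes = np.array([code_of[c] for c in cond_by_day], dtype=np.int8)
    condition = pd.Categorical.from_codes(
        day_codes[np.clip(attr_day, 0, max_day)], categories=cond_categories
    )
    label = pd.Categorical.from_codes(
        is_nta.astype(np.int8), categories=["DTA", "NTA"]
    )

    start_date_ts = pd.Timestamp(design.start_date)
    frame = pd.DataFrame(
        {
            "timestamp": series.counts.index,
            "count": series.counts.to_numpy(),
            "label": label,
            "condition": condition,
            "weekend": weekend,
            "attr_date": start_date_ts + pd.to_timedelta(attr_day - 1, unit="D"),
            "clock_minute": abs_min % MINUTES_PER_DAY,
        }
    )
    return LabeledEpochs(subject_id=series.subject_id, frame=frame)


# ----------------------------------------------------------------------
# Daily profiles
# ----------------------------------------------------------------------
def build_daily_profiles(
    labeled: Iterable[LabeledEpochs] | LabeledEpochs,
    grid_size: int = 1440,
    aggregation: str = "per_condition_mean",
    conditions: tuple[str, ...] = ("drug", "placebo"),
    max_missing_frac: float = 0.2,
) -> list[DailyProfile]:
    """Assemble fixed-grid 24-hour profiles from labeled epochs.

    ``per_condition_mean`` yields one profile per subject x condition:
    each grid cell is the mean count over every member minute of that
    subject's days in that condition (conditions taken from the per-epoch
    attribution, so a night straddling midnight counts toward its onset
    day's condition).  ``per_day`` yields one profile per subject x
    attributed date.  Cells with no covered minutes are NaN; profiles
    with more than ``max_missing_frac`` missing cells are dropped.
    """
    if grid_size < 1 or MINUTES_PER_DAY % grid_size != 0:
        raise ValueError(f"grid_size must divide {MINUTES_PER_DAY}, got {grid_size}")
    if aggregation not in ("per_condition_mean", "per_day"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if isinstance(labeled, LabeledEpochs):
        labeled = [labeled]
    cell_minutes = MINUTES_PER_DAY // grid_size
    profiles: list[DailyProfile] = []
    for lab in labeled:
        f = lab.frame
        cell = (f["clock_minute"].to_numpy() // cell_minutes).astype(np.int64)
        counts = f["count"].to_numpy(float)
        if aggregation == "per_condition_mean":
            for c in conditions:
                m = (f["condition"] == c).to_numpy()
                if not m.any():
                    continue
                prof = _cell_means(cell[m], counts[m], grid_size)
                n_days = int(f.loc[m, "attr_date"].nunique())
                p = DailyProfile(lab.subject_id, c, prof, n_days)
                if 1.0 - p.coverage <= max_missing_frac:
                    profiles.append(p)
        else:
            dates = f["attr_date"].to_numpy()
            cond = np.asarray(f["condition"].astype(str))
            for d in pd.unique(dates):
                m = dates == d
                prof = _cell_means(cell[m], counts[m], grid_size)
                c = cond[m][0]
                p = DailyProfile(
                    lab.subject_id, str(c), prof, 1, date=pd.Timestamp(d).date()
                )
                if 1.0 - p.coverage <= max_missing_frac:
                    profiles.append(p)
    return profiles


def _cell_means(cell: np.ndarray, counts: np.ndarray, grid_size: int) -> np.ndarray:
    tot = np.zeros(grid_size)
    n = np.zeros(grid_size)
    np.add.at(tot, cell, counts)
    np.add.at(n, cell, 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, tot / np.maximum(n, 1), np.nan)


def rebin_profile(profile: DailyProfile, grid_size: int) -> DailyProfile:
    """Re-bin a profile to a coarser grid by averaging whole cells.

    Exact (commutes with direct construction) when every minute of every
    member cell was observed, since all cells then carry equal weight.
    """
    g0 = profile.grid_size
    if g0 % grid_size != 0:
        raise ValueError(f"cannot re-bin grid {g0} to {grid_size}")
    k = g0 // grid_size
    vals = profile.values.reshape(grid_size, k)
    ok = ~np.isnan(vals)
    n = ok.sum(axis=1)
    new = np.where(n > 0, np.where(ok, vals, 0.0).sum(axis=1) / np.maximum(n, 1),
                   np.nan)
    return DailyProfile(
        profile.subject_id, profile.condition, new, profile.n_days, date=profile.date
    )
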