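"""Crossover trial calendar: treatment sequences, periods, washout.

The trial template is a two-period, two-condition crossover: each subject
receives the active drug and placebo for one period each, in randomized
order, separated by a drug-free washout.  Day numbers are 1-based from the
first treatment day; day 0 (and anything earlier) is pre-trial baseline.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

CONDITIONS = ("drug", "placebo")

#: Condition labels an epoch can carry.
BASELINE = "baseline"
WASHOUT = "washout"


class DesignError(ValueError):
    """Raised for invalid trial-design specifications."""


@dataclass(frozen=True)
class TrialDesign:
    """Two-period crossover design with a washout between periods.

    Parameters
    ----------
    sequence
        Mapping from subject id to its ordered pair of condition labels,
        e.g. ``("drug", "placebo")`` for a drug-first subject.
    period_length
        Length of each treatment period in days (default 14).
    washout_length
        Length of the washout separating the periods in days (default 7).
    start_date
        Calendar date of trial day 1 (first day of period 1).
    """

    sequence: Mapping[str, tuple[str, str]]
    period_length: int = 14
    washout_length: int = 7
    start_date: dt.date = field(default=dt.date(2023, 1, 2))

    def __post_init__(self) -> None:
        if self.period_length < 1:
            raise DesignError(f"period_length must be >= 1, got {self.period_length}")
        if self.washout_length < 0:
            raise DesignError(f"washout_length must be >= 0, got {self.washout_length}")
        if not self.sequence:
            raise DesignError("sequence must name at least one subject")
        for sid, seq in self.sequence.items():
            if tuple(sorted(seq)) != tuple(sorted(CONDITIONS)):
                raise DesignError(
                    f"subject {sid!r}: sequence {seq!r} must contain each of "
                    f"{CONDITIONS} exactly once"
                )

    # ------------------------------------------------------------------
    @classmethod
    def randomized(
        cls,
        subject_ids: Sequence[str],
        seed: int | np.random.Generator = 0,
        period_length: int = 14,
        washout_length: int = 7,
        start_date: dt.date = dt.date(2023, 1, 2),
    ) -> "TrialDesign":
        """Assign a balanced randomized sequence (half drug-first)."""
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        ids = list(subject_ids)
        n = len(ids)
        n_drug_first = (n + 1) // 2
        order = rng.permutation(n)
        seq = {}
        for rank, idx in enumerate(order):
            first = "drug" if rank < n_drug_first else "placebo"
            second = "placebo" if first == "drug" else "drug"
            seq[ids[idx]] = (first, second)
        return cls(
            sequence=seq,
            period_length=period_length,
            washout_length=washout_length,
            start_date=start_date,
        )

    # ------------------------------------------------------------------
    @property
    def n_days(self) -> int:
        """Total number of trial days (both periods plus washout)."""
        return 2 * self.period_length + self.washout_length

    @property
    def subjects(self) -> list[str]:
        return list(self.sequence)

    def day_number(self, date: dt.date) -> int:
        """1-based trial day for a calendar date (0 or negative = pre-trial)."""
        return (date - self.start_date).days + 1

    def date_of_day(self, day: int) -> dt.date:
        return self.start_date + dt.timedelta(days=day - 1)

    def condition_of_day(self, subject_id: str, day: int) -> str:
        """Condition label in force on a given 1-based trial day.

        Days at or before 0 are baseline; days beyond the trial span raise.
        """
        if subject_id not in self.sequence:
            raise DesignError(f"unknown subject {subject_id!r}")
        if day <= 0:
            return BASELINE
        if day > self.n_days:
            raise DesignError(
                f"day {day} outside trial span 1..{self.n_days} for {subject_id!r}"
            )
        first, second = self.sequence[subject_id]
        if day <= self.period_length:
            return first
        if day <= self.period_length + self.washout_length:
            return WASHOUT
        return second

    def condition_codes(self, subject_id: str, max_day: int | None = None) -> np.ndarray:
        """Vector of condition labels for days ``0..max_day`` (index = day)."""
        last = self.n_days if max_day is None else max_day
        out = np.empty(last + 1, dtype=object)
        out[0] = BASELINE
        for d in range(1, last + 1):
            out[d] = self.condition_of_day(subject_id, d)
        return out

    def end_of_period_days(self) -> tuple[int, int]:
        """Trial days on which periods 1 and 2 end (assessment days)."""
        return (self.period_length, self.n_days)

    def to_dict(self) -> dict:
        return {
            "period_length": self.period_length,
            "washout_length": self.washout_length,
            "start_date": self.start_date.isoformat(),
            "sequence": {k: list(v) for k, v in self.sequence.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialDesign":
        return cls(
            sequence={k: tuple(v) for k, v in dict(d["sequence"]).items()},
            period_length=int(d.get("period_length", 14)),
            washout_length=int(d.get("washout_length", 7)),
            start_date=dt.date.fromisoformat(d["start_date"])
            if "start_date" in d
            else dt.date(2023, 1, 2),
        )
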