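"""Change-from-baseline analysis of 6-item sleep-quality questionnaires.

Scores collected on days 0 (baseline), 14 and 35 (end of crossover periods
1 and 2) are turned into within-subject change scores for three contrasts
— NSAID-baseline, placebo-baseline and NSAID-placebo — for each item and
for the 5-item and 6-item totals, and tested with matched-pairs t-tests at
a multiplicity-adjusted significance threshold of p < 0.016.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import TrialDesign

log = logging.getLogger(__name__)

ITEMS = tuple(f"q{i}" for i in range(1, 7))
MEASURES = ITEMS + ("total_5q", "total_6q")
MEASURE_LABELS = {
    "q1": "Q1: Movement",
    "q2": "Q2: Twitching",
    "q3": "Q3: Dreaming",
    "q4": "Q4: Shifting position",
    "q5": "Q5: Vocalizing",
    "q6": "Q6: Pacing",
    "total_5q": "Total (Q1-5)",
    "total_6q": "Total (6Q)",
}
CONTRASTS = ("nsaid_vs_baseline", "placebo_vs_baseline", "nsaid_vs_placebo")

#: Multiplicity-adjusted critical p-value; significance requires p strictly
#: below this threshold.
SIGNIFICANCE_THRESHOLD = 0.016

__all__ = [
    "ITEMS",
    "MEASURES",
    "CONTRASTS",
    "SIGNIFICANCE_THRESHOLD",
    "add_totals",
    "change_scores",
    "paired_t",
    "snore_table",
]


def add_totals(responses: pd.DataFrame) -> pd.DataFrame:
    """Append the 5-item (Q1-5) and 6-item total score columns."""
    out = responses.copy()
    out["total_5q"] = out[list(ITEMS[:5])].sum(axis=1)
    out["total_6q"] = out[list(ITEMS)].sum(axis=1)
    return out


def change_scores(responses: pd.DataFrame, design: TrialDesign) -> pd.DataFrame:
    """Per-subject paired differences for each contrast and measure.

    The end-of-period assessments (days ``period_length`` and
    ``2*period_length + washout_length``; 14 and 35 under the default
    design) are mapped to NSAID or placebo via each subject's randomized
    sequence; day 0 is baseline.  Mid-washout/mid-period assessments are
    ignored.  Subjects missing an assessment are dropped from the affected
    contrasts, with a logged count.

    Returns a long frame: subject_id, contrast, measure, difference.
    """
    resp = add_totals(responses)
    d1, d2 = design.end_of_period_days()
    rows = []
    n_dropped = 0
    for sid, grp in resp.groupby("subject_id", sort=True):
        sid = str(sid)
        if sid not in design.sequence:
            raise ValueError(f"subject {sid!r} absent from the trial design")
        by_day = {int(r["day"]): r for _, r in grp.iterrows()}
        first, _ = design.sequence[sid]
        drug_day = d1 if first == "drug" else d2
        placebo_day = d2 if first == "drug" else d1
        base = by_day.get(0)
        drug = by_day.get(drug_day)
        placebo = by_day.get(placebo_day)
        for contrast, hi, lo in (
            ("nsaid_vs_baseline", drug, base),
            ("placebo_vs_baseline", placebo, base),
            ("nsaid_vs_placebo", drug, placebo),
        ):
            if hi is None or lo is None:
                n_dropped += 1
                continue
            for measure in MEASURES:
                rows.append(
                    {
                        "subject_id": sid,
                        "contrast": contrast,
                        "measure": measure,
                        "difference": float(hi[measure]) - float(lo[measure]),
                    }
                )
    if n_dropped:
        log.warning("dropped %d subject-contrasts with missing assessments", n_dropped)
    return pd.DataFrame(rows)


def paired_t(differences: np.ndarray | pd.Series) -> tuple[float, float, float]:
    """One-sample t-test of paired differences against zero.

    Returns ``(mean difference, t, two-sided p)`` with n-1 degrees of
    freedom.  Degenerate zero-variance inputs: all-zero differences give
    ``(0, 0, 1)``; identical nonzero differences give a zero p sentinel
    with a warning.
    """
    d = np.asarray(differences, float)
    n = d.size
    if n < 2:
        raise ValueError(f"need at least 2 paired differences, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.0, 1.0
        warnings.warn(
            "zero-variance differences with nonzero mean: p reported as 0",
            stacklevel=2,
        )
        return mean, float(np.inf) if mean > 0 else float(-np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return mean, float(t), float(p)


@dataclass
class SnoreTestResult:
    """Matched-pairs t-test results for every contrast x measure."""

    table: pd.DataFrame  # rows: measures; columns: per-contrast stats
    threshold: float = SIGNIFICANCE_THRESHOLD

    def significant(self, measure: str, contrast: str) -> bool:
        return bool(self.table.loc[measure, f"{contrast}_significant"])


def snore_table(
    diffs: pd.DataFrame, threshold: float = SIGNIFICANCE_THRESHOLD
) -> SnoreTestResult:
    """Build the per-item / per-total report of matched-pairs t-tests.

    One row per measure (Q1..Q6 and both totals); per contrast, the mean
    within-subject difference, t statistic, two-sided p and a significance
    flag requiring ``p`` strictly below ``threshold`` (boundary values are
    not significant).
    """
    rows = {}
    for measure in MEASURES:
        row: dict[str, float | bool | str] = {"label": MEASURE_LABELS[measure]}
        for contrast in CONTRASTS:
            sel = diffs[
                (diffs["measure"] == measure) & (diffs["contrast"] == contrast)
            ]["difference"]
            if len(sel) >= 2:
                mean, t, p = paired_t(sel)
            else:
                mean, t, p = np.nan, np.nan, np.nan
            row[f"{contrast}_mean_diff"] = mean
            row[f"{contrast}_t"] = t
            row[f"{contrast}_p"] = p
            row[f"{contrast}_significant"] = bool(p < threshold) if np.isfinite(p) else False
        rows[measure] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    return SnoreTestResult(table=table, threshold=threshold)
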