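"""Summary-statistic comparison arm: night/day means and mixed models.

This arm reproduces the traditional analysis that functional modeling is
contrasted against: collapse each subject-day into a single mean count per
minute for the night (NTA) and day (DTA) segments, then fit a linear
mixed-effects model of the (transformed, standardized) segment mean on
age, weight, sex, baseline pain score (CBPI), weekend and treatment, with
a random intercept per subject.  Model-averaged coefficients are computed
over all subsets of the six fixed effects with small-sample AIC (AICc)
weights and full (zero-substitution) averaging.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import LabeledEpochs

FIXED_EFFECTS = ("age", "weight", "sex", "cbpi", "weekend", "treatment")

__all__ = [
    "FIXED_EFFECTS",
    "LMMFit",
    "AveragedCoefficients",
    "summarize_day_night",
    "fit_lmm",
    "model_average",
]


def summarize_day_night(
    labeled: Iterable[LabeledEpochs] | LabeledEpochs,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per subject-date-segment mean activity, one row each.

    The "date" of a night (NTA) row is the night's evening-onset date, so
    a whole night is one row even though it straddles midnight.  Washout
    and baseline rows are retained but flagged via ``condition``; they are
    excluded from treatment contrasts by :func:`fit_lmm`.  If
    ``covariates`` is given (subject_id, age, weight, sex, cbpi) it is
    merged onto the rows.
    """
    if isinstance(labeled, LabeledEpochs):
        labeled = [labeled]
    frames = []
    for lab in labeled:
        f = lab.frame
        g = (
            f.groupby(["label", "attr_date"], sort=True, observed=True)
            .agg(
                mean_count=("count", "mean"),
                n_minutes=("count", "size"),
                weekend=("weekend", "first"),
                condition=("condition", "first"),
            )
            .reset_index()
        )
        g.insert(0, "subject_id", lab.subject_id)
        frames.append(g)
    table = pd.concat(frames, ignore_index=True)
    table = table.rename(columns={"label": "segment", "attr_date": "date"})
    table = table[
        ["subject_id", "date", "segment", "mean_count", "n_minutes", "weekend",
         "condition"]
    ]
    if covariates is not None:
        table = table.merge(
            covariates[["subject_id", "age", "weight", "sex", "cbpi"]],
            on="subject_id",
            how="left",
        )
    return table


# ----------------------------------------------------------------------
@dataclass
class LMMFit:
    """A single mixed-model fit: coefficient table plus diagnostics."""

    params: pd.DataFrame  # index = effect; Estimate, Standard Error, z-value, P(>|z|)
    segment: str
    n_obs: int
    n_subjects: int
    converged: bool
    singular: bool
    llf: float
    random_intercept_var: float

    def pvalue(self, effect: str) -> float:
        return float(self.params.loc[effect, "P(>|z|)"])

    def estimate(self, effect: str) -> float:
        return float(self.params.loc[effect, "Estimate"])


@dataclass
class AveragedCoefficients:
    """Model-averaged fixed effects over a candidate set of mixed models."""

    table: pd.DataFrame  # index = effect; Estimate, Standard Error, z-value, P(>|z|)
    candidates: pd.DataFrame  # one row per candidate: effects, llf, aicc, weight
    segment: str

    def pvalue(self, effect: str) -> float:
        return float(self.table.loc[effect, "P(>|z|)"])

    def estimate(self, effect: str) -> float:
        return float(self.table.loc[effect, "Estimate"])


def _prepare(
    table: pd.DataFrame, segment: str, transform: str
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Response vector, standardized design frame and subject groups."""
    seg = table[
        (table["segment"] == segment) & table["condition"].isin(["drug", "placebo"])
    ].copy()
    if seg.empty:
        raise ValueError(f"no drug/placebo rows for segment {segment!r}")
    if seg["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    missing = [c for c in ("age", "weight", "sex", "cbpi") if c not in seg.columns]
    if missing:
        raise ValueError(f"summary table lacks covariates {missing}")

    y = seg["mean_count"].to_numpy(float)
    if transform == "log1p":
        y = np.log1p(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    ysd = y.std(ddof=0)
    y = (y - y.mean()) / (ysd if ysd > 0 else 1.0)

    X = pd.DataFrame(index=seg.index)
    for col in ("age", "weight", "cbpi"):
        v = seg[col].to_numpy(float)
        sd = v.std(ddof=0)
        X[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    X["sex"] = (seg["sex"].astype(str).str.upper() == "M").astype(float)
    X["weekend"] = seg["weekend"].astype(float)
    X["treatment"] = (seg["condition"] == "drug").astype(float)
    groups = seg["subject_id"].to_numpy()
    return y, X, groups


def _fit_one(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    effects: Sequence[str],
    reml: bool,
) -> tuple[sm.regression.mixed_linear_model.MixedLMResults, bool]:
    exog = sm.add_constant(X[list(effects)], has_constant="add")
    model = sm.MixedLM(y, exog, groups=groups)
    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(reml=reml, method="lbfgs")
        try:
            if float(res.cov_re.iloc[0, 0]) <= 1e-10:
                singular = True
        except Exception:
            singular = True
    return res, singular


def fit_lmm(
    table: pd.DataFrame,
    segment: str = "NTA",
    transform: str = "log1p",
    effects: Sequence[str] = FIXED_EFFECTS,
) -> LMMFit:
    """Fit the full linear mixed-effects model for one segment.

    Response: z-scored (optionally log1p) segment mean count.  Fixed
    effects: age, weight, sex, CBPI (continuous ones z-scored), weekend
    and treatment indicators.  Random intercept per subject, restricted
    maximum likelihood.  A singular (zero) random-intercept variance is
    reported via the ``singular`` flag with a warning.
    """
    y, X, groups = _prepare(table, segment, transform)
    res, singular = _fit_one(y, X, groups, effects, reml=True)
    if singular:
        warnings.warn(
            f"segment {segment}: random-intercept variance degenerate (reported 0)",
            stacklevel=2,
        )
    rows = {}
    for eff in effects:
        est = float(res.params[eff])
        se = float(res.bse[eff])
        z = abs(est) / se if se > 0 else np.inf
        rows[eff] = {
            "Estimate": est,
            "Standard Error": se,
            "z-value": z,
            "P(>|z|)": 2.0 * sps.norm.sf(z),
        }
    params = pd.DataFrame.from_dict(rows, orient="index")
    re_var = float(res.cov_re.iloc[0, 0]) if not singular else 0.0
    return LMMFit(
        params=params,
        segment=segment,
        n_obs=len(y),
        n_subjects=int(pd.unique(groups).size),
        converged=bool(res.converged),
        singular=singular,
        llf=float(res.llf),
        random_intercept_var=re_var,
    )


def model_average(
    table: pd.DataFrame,
    segment: str = "NTA",
    candidates: Sequence[Sequence[str]] | None = None,
    transform: str = "log1p",
) -> AveragedCoefficients:
    """Model-averaged coefficients over candidate fixed-effect subsets.

    Every candidate (default: all 2^6 subsets of the six fixed effects,
    each with intercept and subject random intercept) is fitted by maximum
    likelihood; AICc weights are formed; estimates are full-averaged with
    zero substitution for absent effects, and unconditional standard
    errors combine within-model variance and between-model spread.  Wald
    z and two-sided normal p-values are reported per effect.  Candidates
    that fail to fit are dropped (with a warning) and weights
    renormalized.
    """
    y, X, groups = _prepare(table, segment, transform)
    if candidates is None:
        candidates = [
            combo
            for r in range(len(FIXED_EFFECTS) + 1)
            for combo in itertools.combinations(FIXED_EFFECTS, r)
        ]
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    n = len(y)
    cand_rows = []
    fits = []
    for effects in candidates:
        try:
            res, _ = _fit_one(y, X, groups, effects, reml=False)
            llf = float(res.llf)
            if not np.isfinite(llf):
                raise ValueError("non-finite log-likelihood")
        except Exception as exc:  # noqa: BLE001 — candidate dropped, not fatal
            warnings.warn(f"candidate {effects!r} dropped: {exc}", stacklevel=2)
            continue
        k = len(effects) + 3  # intercept + fixed effects + RE var + residual var
        aic = -2.0 * llf + 2.0 * k
        aicc = aic + (2.0 * k * (k + 1)) / max(n - k - 1, 1)
        fits.append((tuple(effects), res))
        cand_rows.append({"effects": "+".join(effects) or "(intercept)",
                          "k": k, "llf": llf, "aicc": aicc})
    if not fits:
        raise ValueError("all candidate models failed to fit")
    cand = pd.DataFrame(cand_rows)
    delta = cand["aicc"] - cand["aicc"].min()
    w = np.exp(-0.5 * delta.to_numpy())
    w = w / w.sum()
    cand["weight"] = w

    rows = {}
    for eff in FIXED_EFFECTS:
        est = np.zeros(len(fits))
        var = np.zeros(len(fits))
        for i, (effects, res) in enumerate(fits):
            if eff in effects:
                est[i] = float(res.params[eff])
                var[i] = float(res.bse[eff]) ** 2
        avg = float(np.sum(w * est))
        se = float(np.sqrt(np.sum(w * (var + (est - avg) ** 2))))
        z = abs(avg) / se if se > 0 else (np.inf if avg != 0 else 0.0)
        rows[eff] = {
            "Estimate": avg,
            "Standard Error": se,
            "z-value": z,
            "P(>|z|)": 2.0 * sps.norm.sf(z) if np.isfinite(z) else (0.0 if z else 1.0),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    return AveragedCoefficients(table=out, candidates=cand, segment=segment)
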