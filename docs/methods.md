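# Methods

This note documents the models, algorithms and design choices behind
`actiflm`: what is computed, under which assumptions, and where the design
was genuinely open.

## 1. The functional analysis

### Profiles and smoothing

For each subject × condition the minute epochs attributed to that condition
are averaged onto a fixed clock grid (default G = 144 cells of 10 minutes;
G = 1440 available). Cell values are mean counts/min over all member
minutes; cells with no coverage are missing, and profiles with more than
20% missing cells are rejected (configurable).

Profiles are smoothed by penalized least squares on a **circular B-spline
basis**: `n_basis = 24` translates of the cardinal cubic B-spline wrapped
on the 1440-minute clock (a partition of unity, so constants are
represented exactly), with a cyclic second-difference penalty on the
coefficients. Circularity is enforced because clock time is periodic — the
fitted curve and its derivative are continuous across midnight by
construction. The penalty weight λ is selected per profile by generalized
cross-validation over a fixed grid `10^-4 … 10^6` (21 log-spaced points);
n·RSS/(n − edf)² is minimized, with edf the trace of the hat matrix.
Counts are `log1p`-transformed before smoothing by default (variance
stabilization for overdispersed counts); the identity transform is a
configuration option.

Open choices resolved here: the basis dimension and whether smoothing
happens before or after averaging days are not externally fixed; the
package smooths the per-condition mean profile (one curve per subject per
condition) with B = 24, and exposes both `per_condition_mean` and
`per_day` aggregations plus the basis spec in configuration.

### Point-wise permutation F-test

At each grid point the two-group one-way ANOVA F statistic is computed on
the curve evaluations. Degenerate points: zero within-group variance with
nonzero between-group variance yields an `inf` sentinel; zero/zero yields
F = 0.

The null distribution is generated by permuting condition labels:

* **paired** (default): the two labels are independently swapped or kept
  within each subject — the 2^n sign-flip group appropriate to a
  crossover, where the subject is the exchangeable unit;
* **unpaired**: all labels are shuffled preserving group sizes (a naive
  two-group comparison, provided for contrast);
* `method="exhaustive"` enumerates all 2^n paired assignments (n ≤ 20)
  instead of sampling `n_perm = 500` of them.

The p-curve uses the strict "greater than" counting rule
(p(t) = #{F_perm(t) > F_obs(t)} / n_perm), so p-values live on
{0, 1/n_perm, …, 1}; the more conservative (1+b)/(1+n) convention is a
flag (`p_rule="add_one"`). The critical curve is the nearest-rank
empirical (1−α) quantile of the permutation values at each point, and
significance requires the strict inequality F_obs > crit. With sampled
sign-flips this makes the point-wise rejection probability under
exchangeability (n_perm − rank)/(n_perm + 1) = 25/501 ≈ 0.0499 at
α = 0.05, n_perm = 500 — verified empirically by the calibration study.

Significant intervals are maximal runs of significant grid points, merged
across midnight into wrapped intervals, optionally dropped below a minimum
length, and annotated with the condition whose mean curve is higher over
the run. Note that with a point-wise (not family-wise) test, isolated
spurious cells are expected at rate α even under the null; interval lists
from a single run should be read accordingly, and a long run annotated
with one direction can span sub-regions where the sign differs.

## 2. The summary arm

Each subject-date-segment (NTA/DTA) becomes one row with its mean
count/min. A night's row is keyed by the night's evening-onset date, so a
night straddling midnight is a single observation attributed to the
condition in force that evening. The model is

    z(log1p(mean_count)) ~ age + weight + sex + cbpi + weekend + treatment
                           + (1 | subject)

with continuous covariates z-scored, fitted by REML (single fit) or ML
(model averaging). Model averaging is the all-subsets flavor: all 64
subsets of the six fixed effects, AICc weights
(k = fixed effects + intercept + 2 variance parameters), full averaging
with zero substitution, and unconditional standard errors combining
within-model variance and between-model spread; Wald z and two-sided
normal p-values. This is the field-standard recipe for model-averaged
coefficient tables; the information criterion (AICc) and the full-averaging
flavor are this package's own choices, documented here. Candidates that
fail to fit are dropped with a warning and weights renormalized.

Standardizing both response and continuous covariates makes coefficients
unit-free (so, e.g., rescaling weight from kg to g leaves the reported
coefficient, z and p unchanged).

## 3. The questionnaire arm

Scores from the 6-item instrument on the baseline day and the two
end-of-period days are mapped to conditions via each subject's randomized
sequence; mid-washout and mid-period assessments are ingested but unused.
Three contrasts per measure (six items plus the 5-item and 6-item totals)
are tested with one-sample t-tests on within-subject differences, df =
n−1, two-sided. Significance uses the multiplicity-adjusted threshold
p < 0.016 with a *strict* inequality (a boundary p of exactly 0.016 is not
significant). Degenerate inputs: all-zero differences give (t, p) = (0, 1);
identical nonzero differences give a p = 0 sentinel with a warning.

## 4. The synthetic generator

The generator emulates the trial design the analysis targets: 15 dogs
(10 F / 5 M; age 10.29 ± 2.48 y, weight 31.53 ± 5.39 kg, baseline CBPI
3.85 ± 1.5), two 14-day periods separated by a 7-day washout, balanced
randomized sequences, day 1 anchored to a Monday so the two periods have
identical weekend composition (this makes drug and placebo exactly
exchangeable under a null model, the basis of the calibration study).

Minute counts follow a gamma–Poisson (negative-binomial-type) law with
log-mean

    intercept + Σ_h amp_h cos(2π(t − phase_h)/period_h)   [cosinor]
    + b_subject                                            [N(0, 0.3²)]
    + log(weekend_multiplier) · [weekend date]             [default 1.15]
    + log(m_w) · [drug condition ∧ t ∈ window w]

and variance = `dispersion` × mean (default 3, typical accelerometer
overdispersion; 1 recovers Poisson). The default cosinor (intercept
log 30, 24-h amplitude 1.4 peaking 14:00, 12-h amplitude 0.4) gives a
mid-afternoon peak near 80 counts/min, a deep trough near 5 counts/min at
02:00, and a shallow midday lull — a realistic unimodal dog day. Two
harmonics are the smallest family with this shape; more are configurable.

Treatment windows live on a circular 1440-minute clock with wraparound
(start > end spans midnight). Minutes before noon are attributed to the
previous calendar day's condition ("circadian day" anchored on the evening
dose), so a 23:00–06:00 window sits inside one condition; the classifier's
night-onset attribution agrees with this for night epochs, while morning
daytime epochs on the three period-transition days are attributed to the
calendar day — a small, realistic carryover-like contamination. The
default windows emulate an analgesic: ×0.5 on 23:00–06:00 and ×1.3 on
07:00–12:00 under drug. An optional evening ramp decays the drug effect
toward 1 in the hour before the 18:00 dose (off by default).

Diaries: one bed and rise time per night, truncated normals (bed
23:00 ± 30 min, rise 06:30 ± 30 min, ±2 h truncation; no external
distribution exists, these are chosen as typical owner-reported values).
A bed time drawn past midnight is recorded as 23:59 so the evening-onset
convention stays exact (≈2% of nights).

Questionnaire scores are `baseline_i + u_subject,i + shift_i(condition) +
noise`, with variance split by a within-subject correlation (default 0.5)
and clamped to 0–10. The response scale of the real instrument is not
documented; the generator defaults to a *continuous* 0–10 scale (an
integer-rounding option exists) because rounding breaks exact mean-shift
recovery, which the validation suite relies on. Default shifts make items
2–3 (twitching/dreaming) most drug-responsive and item 6 unresponsive.

### What the generator does not emulate

Accelerometer hardware artifacts (axis signals, nonwear, device
placement), owner noncompliance, pharmacokinetics beyond the optional
evening ramp, seasonal/weather trends, and period or carryover effects.
Passing tests therefore demonstrate the *statistical machinery* —
calibration, recovery, the functional-vs-summary contrast — under the
stated generative assumptions, not robustness to real-world artifacts.

## 5. Epoch classification and conventions

* Night interval is half-open `[bed, rise)` on the circular clock: the
  bed-time minute is NTA, the rise-time minute is DTA, making the
  NTA/DTA partition exact.
* A night wraps past midnight iff rise ≤ bed on the clock (a same-date
  afternoon "night" like 13:00–14:00 is accepted without wrapping).
* Weekend: an NTA night is weekend iff its onset date is Friday or
  Saturday; a DTA day iff the calendar date is Saturday or Sunday.
* Nights missing from the diary fall back to a fixed 00:00–05:00 window
  (the designated night-time of the precursor summary analysis).
* Timestamps are naive local clock time; no timezone/DST arithmetic (the
  design is a 5-week local trial).
* No nonwear detection; missing minutes are handled purely by coverage
  accounting.

## 6. Numerical choices and degenerate inputs

* GCV denominator guarded at 1e-8; RSS floored at 0.
* Nearest-rank quantile for the critical curve; strict inequalities for
  both significance and p-counting (ties are measure-zero for continuous
  curves).
* Re-binning a profile to a coarser grid averages whole cells and
  commutes exactly with direct construction only under uniform per-cell
  coverage (e.g. per-day profiles under a fixed night window); with
  diary-varying attribution boundary cells carry unequal weights and the
  identity is approximate.
* Mixed-model fits with degenerate random-intercept variance are reported
  with variance 0 and flagged; model-averaging candidates that fail are
  dropped and weights renormalized.
* Master seed: every pipeline stage draws from children of one
  `numpy.random.SeedSequence`, so arms are independently re-runnable yet
  jointly reproducible; integer outputs are bit-identical across runs.

## 7. Validation studies and problem sizes

The acceptance suite (`tests/test_acceptance.py`,
`scripts/acceptance.py`) uses these study sizes, chosen to estimate each
operating characteristic with useful Monte-Carlo precision:

* **Type-I calibration**: 200 null trials × 500 permutations at G = 144;
  the mean fraction of significant points must match α = 0.05 within 3
  Monte-Carlo SE.
* **Permutation oracle**: 4 paired subjects, all 16 assignments
  enumerated vs a sampler forced to visit each — exact distributional
  equality.
* **F oracle**: 25 random instances against an independent scalar ANOVA
  at 1e-10 relative tolerance.
* **Window recovery**: 50 trials with the default injected windows;
  median circular Jaccard of detected vs injected ≥ 0.6 with matching
  directions. (Smoothing blurs window edges by roughly the 1-hour knot
  spacing, which bounds the achievable overlap below 1.)
* **Functional-vs-summary contrast**: 100 trials with a mean-preserving
  redistribution (01:00–02:00 × 0.5, 02:00–03:00 × 1.5 — equal-length
  windows symmetric about the 02:00 circadian trough, so the expected
  whole-night mean is unchanged); the summary model's treatment term must
  reject in <20% of replicates while the functional test flags the
  injected windows in >80%.
* **Summary-arm recovery**: 100 trials, weekend multiplier 1.2, null
  treatment; the model-averaged weekend coefficient positive and
  significant in >80% of replicates, treatment rejection within 3
  binomial SE of 5%. (The weekend/night attribution conventions overlap
  imperfectly — ~85% of weekend-night minutes carry the multiplier — so
  the estimated weekend effect is mildly attenuated but decisively
  nonzero at these sizes.)

## 8. Known limitations

* The point-wise test controls error per clock point, not family-wise;
  no band/max-statistic test is provided (out of scope by design).
* Model averaging assumes the AICc/full-averaging flavor; other flavors
  (conditional averaging, BIC weights) would give different tables.
* The LMM treats nights as conditionally independent given the subject
  intercept; no serial correlation across nights is modeled.
* Direction annotation assigns one direction per interval; long merged
  intervals can span regions of opposite sign.
* The generator's exchangeability under the null is exact only because
  periods have identical weekend composition; designs starting mid-week
  break this slightly.
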