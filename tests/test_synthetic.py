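"""Generator behavior: cohort moments, count law, effect windows, diaries."""

import numpy as np
import pandas as pd
import pytest

from actiflm.design import TrialDesign
from actiflm.synthetic import (
    ActivityModel,
    CohortSpec,
    SnoreEffectSpec,
    SpecValidationError,
    simulate_activity,
    simulate_cohort,
    simulate_snore,
    window_mask,
)

MIN_PER_DAY = 1440


class TestCohort:
    def test_large_sample_moments_match_spec(self):
        spec = CohortSpec(n_subjects=10_000, n_female=6_667, n_male=3_333)
        cohort = simulate_cohort(spec, seed=7)
        se_age = spec.age_sd / np.sqrt(spec.n_subjects)
        assert abs(cohort["age"].mean() - spec.age_mean) < 2 * se_age
        se_w = spec.weight_sd / np.sqrt(spec.n_subjects)
        assert abs(cohort["weight"].mean() - spec.weight_mean) < 2 * se_w
        assert (cohort["sex"] == "F").sum() == 6_667

    def test_zero_sd_gives_identical_subjects(self):
        spec = CohortSpec(
            n_subjects=5, n_female=5, n_male=0, age_sd=0, weight_sd=0, cbpi_sd=0
        )
        cohort = simulate_cohort(spec, seed=1)
        for col, mean in (("age", 10.29), ("weight", 31.53), ("cbpi", 3.85)):
            assert np.allclose(cohort[col], mean)

    def test_same_seed_is_deterministic(self):
        spec = CohortSpec()
        pd.testing.assert_frame_equal(
            simulate_cohort(spec, seed=3), simulate_cohort(spec, seed=3)
        )

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_subjects": 1, "n_female": 1, "n_male": 0}, "n_subjects"),
            ({"age_sd": -1.0}, "age_sd"),
            ({"n_female": 3, "n_male": 3}, "n_female"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises(SpecValidationError, match=field):
            CohortSpec(**kwargs)


class TestActivity:
    def test_flat_model_recovers_grand_mean(self, small_cohort, small_design):
        """With no harmonics and no effects the empirical grand mean count
        converges to exp(intercept) (law of large numbers)."""
        mu = 20.0
        model = ActivityModel(
            intercept=np.log(mu), harmonics=(), subject_sd=0.0,
            weekend_multiplier=1.0, effect_windows=(),
        )
        cohort = small_cohort.iloc[:5]
        series, _ = simulate_activity(cohort, small_design, model, seed=5)
        counts = np.concatenate([s.counts.to_numpy() for s in series.values()])
        assert counts.size >= 10**5
        se = np.sqrt(model.dispersion * mu / counts.size)
        assert abs(counts.mean() - mu) < 4 * se

    def test_overdispersion_matches_dispersion_parameter(self, small_design):
        mu, phi = 20.0, 3.0
        model = ActivityModel(
            intercept=np.log(mu), harmonics=(), subject_sd=0.0,
            weekend_multiplier=1.0, effect_windows=(), dispersion=phi,
        )
        cohort = pd.DataFrame(
            {"subject_id": ["d01"], "age": [10], "weight": [30], "sex": ["F"],
             "cbpi": [4]}
        )
        series, _ = simulate_activity(cohort, small_design, model, seed=9)
        c = series["d01"].counts.to_numpy()
        assert abs(c.var() / c.mean() - phi) < 0.2

    def test_wrapped_night_window_halves_drug_counts(self):
        """Injecting a x0.5 multiplier on the wrapped 23:00-06:00 window
        halves the in-window drug/placebo mean ratio (direct mean oracle)."""
        spec = CohortSpec(n_subjects=8, n_female=5, n_male=3)
        cohort = simulate_cohort(spec, seed=11)
        design = TrialDesign.randomized(list(cohort["subject_id"]), seed=12)
        model = ActivityModel(effect_windows=((1380.0, 360.0, 0.5),))
        series, _ = simulate_activity(cohort, design, model, seed=13)

        ratios = []
        n_min = design.n_days * MIN_PER_DAY
        minute = np.arange(n_min)
        clock = minute % MIN_PER_DAY
        day = minute // MIN_PER_DAY + 1
        anchor = np.where(clock >= 720, day, day - 1)
        in_win = window_mask(clock, 1380, 360)
        for sid, s in series.items():
            cond = design.condition_codes(sid)[anchor]
            c = s.counts.to_numpy()
            drug = c[in_win & (cond == "drug")].mean()
            placebo = c[in_win & (cond == "placebo")].mean()
            ratios.append(drug / placebo)
        # >100 simulated nights in total; subject effects cancel within pairs
        assert abs(np.mean(ratios) - 0.5) < 0.02

    def test_multiplier_one_window_is_identity(self, small_cohort, small_design):
        model_null = ActivityModel(effect_windows=())
        model_one = ActivityModel(effect_windows=((1380.0, 1440.0, 1.0),))
        s0, d0 = simulate_activity(small_cohort, small_design, model_null, seed=21)
        s1, d1 = simulate_activity(small_cohort, small_design, model_one, seed=21)
        for sid in s0:
            assert s0[sid] == s1[sid]
        pd.testing.assert_frame_equal(d0, d1)

    def test_weekend_multiplier_recovered(self, small_cohort):
        design = TrialDesign.randomized(list(small_cohort["subject_id"]), seed=31)
        model = ActivityModel(
            harmonics=(), subject_sd=0.0, weekend_multiplier=1.3, effect_windows=()
        )
        series, _ = simulate_activity(small_cohort, design, model, seed=32)
        start = np.datetime64(design.start_date)
        wk, wd = [], []
        for s in series.values():
            dates = s.counts.index.to_numpy().astype("datetime64[D]")
            dow = (dates - dates.astype("datetime64[W]")).astype(int)  # Thu=0 epoch
            weekday = pd.DatetimeIndex(s.counts.index).weekday.to_numpy()
            wk.append(s.counts.to_numpy()[weekday >= 5])
            wd.append(s.counts.to_numpy()[weekday < 5])
        ratio = np.concatenate(wk).mean() / np.concatenate(wd).mean()
        assert abs(ratio - 1.3) < 0.04

    def test_counts_are_nonnegative_integers(self, small_trial):
        for s in small_trial["series"].values():
            c = s.counts.to_numpy()
            assert c.dtype.kind == "i"
            assert (c >= 0).all()

    def test_same_seed_bit_identical(self, small_cohort, small_design):
        model = ActivityModel()
        s0, d0 = simulate_activity(small_cohort, small_design, model, seed=41)
        s1, d1 = simulate_activity(small_cohort, small_design, model, seed=41)
        for sid in s0:
            assert (s0[sid].counts.to_numpy() == s1[sid].counts.to_numpy()).all()
        pd.testing.assert_frame_equal(d0, d1)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(SpecValidationError, match="overlap"):
            ActivityModel(effect_windows=((1380.0, 360.0, 0.5), (300.0, 420.0, 1.2)))

    def test_empty_cohort_rejected(self, small_design):
        with pytest.raises(SpecValidationError, match="cohort"):
            simulate_activity(pd.DataFrame(), small_design, ActivityModel(), seed=0)


class TestSnore:
    def test_zero_shifts_give_zero_expected_change(self, small_cohort, small_design):
        effects = SnoreEffectSpec(
            drug_shifts=(0.0,) * 6, placebo_shifts=(0.0,) * 6
        )
        resp = simulate_snore(small_cohort, small_design, effects, seed=51)
        p1_end = small_design.period_length
        base = resp[resp["day"] == 0].set_index("subject_id")
        end1 = resp[resp["day"] == p1_end].set_index("subject_id")
        diffs = (end1[[f"q{i}" for i in range(1, 7)]]
                 - base[[f"q{i}" for i in range(1, 7)]])
        assert abs(diffs.to_numpy().mean()) < 0.5  # zero-mean noise only

    def test_large_sample_recovers_drug_shift(self):
        """Mean (drug - baseline) change on item 3 converges to the injected
        -1.8 shift when item noise is small and n is large."""
        spec = CohortSpec(n_subjects=400, n_female=267, n_male=133)
        cohort = simulate_cohort(spec, seed=61)
        design = TrialDesign.randomized(list(cohort["subject_id"]), seed=62)
        effects = SnoreEffectSpec(item_sds=(0.3,) * 6)
        resp = simulate_snore(cohort, design, effects, seed=63)
        d1, d2 = design.end_of_period_days()
        diffs = []
        for sid, grp in resp.groupby("subject_id"):
            first, _ = design.sequence[sid]
            drug_day = d1 if first == "drug" else d2
            by_day = grp.set_index("day")
            diffs.append(by_day.loc[drug_day, "q3"] - by_day.loc[0, "q3"])
        assert abs(np.mean(diffs) - (-1.80)) < 0.05

    def test_schedule_and_determinism(self, small_cohort, small_design):
        effects = SnoreEffectSpec()
        r0 = simulate_snore(small_cohort, small_design, effects, seed=71)
        r1 = simulate_snore(small_cohort, small_design, effects, seed=71)
        pd.testing.assert_frame_equal(r0, r1)
        assert len(r0) == len(small_cohort) * r0["day"].nunique()

    def test_default_design_uses_paper_schedule(self, small_cohort):
        design = TrialDesign.randomized(list(small_cohort["subject_id"]), seed=72)
        resp = simulate_snore(small_cohort, design, SnoreEffectSpec(), seed=73)
        assert sorted(resp["day"].unique()) == [0, 14, 21, 28, 35]

    def test_scores_respect_scale(self, small_cohort, small_design):
        effects = SnoreEffectSpec(item_sds=(4.0,) * 6)
        resp = simulate_snore(small_cohort, small_design, effects, seed=81)
        q = resp[[f"q{i}" for i in range(1, 7)]].to_numpy()
        assert q.min() >= 0.0 and q.max() <= 10.0
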