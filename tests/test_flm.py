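"""Smoothing, point-wise F, permutation machinery, interval extraction."""

import numpy as np
import pytest
from scipy import stats as sps

from actiflm.flm import (
    BasisSpec,
    FLMResult,
    extract_significant_intervals,
    permute_labels,
    pointwise_F,
    pointwise_permutation_test,
    smooth_profile,
)
from actiflm.io import DailyProfile


def _profile(values, subject="s1", condition="drug", n_days=1):
    return DailyProfile(subject, condition, np.asarray(values, float), n_days)


class TestSmoothing:
    @pytest.mark.parametrize("n_basis", [8, 24])
    def test_constant_profile_fits_exactly(self, n_basis):
        p = _profile(np.full(144, 5.0))
        curve = smooth_profile(p, BasisSpec(n_basis=n_basis), transform="none")
        assert np.allclose(curve.evaluate_grid(144), 5.0)
        assert np.allclose(curve.evaluate(np.array([0.0, 1.3, 1439.9])), 5.0)

    def test_pure_cosine_recovered_below_one_percent(self):
        """A 24-hour cosine sampled at minute resolution is reproduced by a
        24-function cubic circular basis to <1% of its amplitude."""
        t = (np.arange(1440) + 0.5)
        target = np.cos(2 * np.pi * (t - 840) / 1440)
        p = _profile(target + 1.5)  # keep values positive for realism
        curve = smooth_profile(p, BasisSpec(n_basis=24), transform="none")
        fit = curve.evaluate(t)
        assert np.max(np.abs(fit - (target + 1.5))) < 0.01

    def test_log1p_of_zero_profile_is_zero(self):
        p = _profile(np.zeros(144))
        curve = smooth_profile(p, transform="log1p")
        assert np.allclose(curve.evaluate_grid(144), 0.0, atol=1e-10)

    def test_circular_continuity_at_midnight(self):
        rng = np.random.default_rng(3)
        p = _profile(rng.gamma(2.0, 10.0, 144))
        curve = smooth_profile(p)
        eps = 1e-6
        left = curve.evaluate(np.array([1440.0 - eps]))[0]
        right = curve.evaluate(np.array([0.0 + eps]))[0]
        assert abs(left - right) < 1e-3
        dleft = (curve.evaluate(np.array([1440.0 - eps]))[0]
                 - curve.evaluate(np.array([1440.0 - 1 - eps]))[0])
        dright = (curve.evaluate(np.array([1.0 + eps]))[0]
                  - curve.evaluate(np.array([0.0 + eps]))[0])
        assert abs(dleft - dright) < 1e-2

    def test_too_few_cells_rejected(self):
        vals = np.full(144, np.nan)
        vals[:10] = 1.0
        with pytest.raises(ValueError, match="basis"):
            smooth_profile(_profile(vals), BasisSpec(n_basis=24))

    def test_missing_cells_are_ignored(self):
        vals = np.full(144, 4.0)
        vals[30:40] = np.nan
        curve = smooth_profile(_profile(vals), transform="none")
        assert np.allclose(curve.evaluate_grid(144), 4.0, atol=1e-8)


class TestPointwiseF:
    def test_identical_groups_give_zero(self):
        A = np.random.default_rng(1).normal(size=(4, 20))
        assert np.allclose(pointwise_F(A, A.copy()), 0.0)

    def test_hand_computed_constant_groups(self):
        """{1,2,3} vs {4,5,6} at every point: SSB=13.5, SSW/df=1 -> F=13.5."""
        A = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 7))
        B = np.tile(np.array([[4.0], [5.0], [6.0]]), (1, 7))
        assert np.allclose(pointwise_F(A, B), 13.5)

    def test_matches_scalar_anova_oracle(self):
        """Per-point agreement with scipy's one-way ANOVA on 20 random
        instances to 1e-10 relative tolerance."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            na, nb = rng.integers(2, 8, size=2)
            G = int(rng.integers(3, 30))
            A = rng.normal(size=(na, G)) * rng.gamma(2.0)
            B = rng.normal(loc=rng.normal(), size=(nb, G))
            F = pointwise_F(A, B)
            for t in range(G):
                expected = sps.f_oneway(A[:, t], B[:, t]).statistic
                assert F[t] == pytest.approx(expected, rel=1e-10)

    def test_zero_within_variance_sentinels(self):
        A = np.ones((3, 4))
        B = np.full((3, 4), 2.0)
        assert np.all(np.isinf(pointwise_F(A, B)))
        assert np.allclose(pointwise_F(A, A.copy()), 0.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(5, 12))
        B = rng.normal(size=(4, 12))
        assert np.allclose(pointwise_F(A, B), pointwise_F(A + 100.0, B + 100.0))

    def test_group_symmetry(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(5, 12))
        B = rng.normal(size=(4, 12))
        assert np.allclose(pointwise_F(A, B), pointwise_F(B, A))


class TestPermutations:
    def _paired_setup(self, n_subjects):
        labels, subjects = [], []
        for i in range(n_subjects):
            subjects += [f"s{i}", f"s{i}"]
            labels += ["drug", "placebo"]
        return np.array(labels, object), np.array(subjects, object)

    def test_paired_assignment_space(self):
        """15 paired subjects span 2^15 = 32768 distinct assignments."""
        labels, subjects = self._paired_setup(15)
        assert 2 ** 15 == 32768
        seen = {
            tuple(permute_labels(labels, subjects, "paired", rng=seed))
            for seed in range(200)
        }
        assert 1 < len(seen) <= 32768

    def test_identity_is_reachable(self):
        labels, subjects = self._paired_setup(4)
        seen = {
            tuple(permute_labels(labels, subjects, "paired", rng=s))
            for s in range(200)
        }
        assert tuple(labels) in seen
        assert len(seen) == 16  # all assignments visited

    def test_fixed_seed_reproducible_stream(self):
        labels, subjects = self._paired_setup(6)
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        for _ in range(10):
            a = permute_labels(labels, subjects, "paired", rng1)
            b = permute_labels(labels, subjects, "paired", rng2)
            assert (a == b).all()

    def test_unmatched_subjects_rejected(self):
        labels = np.array(["drug", "placebo", "drug"], object)
        subjects = np.array(["a", "a", "b"], object)
        with pytest.raises(ValueError, match="paired"):
            permute_labels(labels, subjects, "paired", rng=0)

    def test_unpaired_preserves_group_sizes(self):
        labels, subjects = self._paired_setup(5)
        out = permute_labels(labels, subjects, "unpaired", rng=1)
        assert (out == "drug").sum() == 5


def _paired_profiles(rng, n_subjects, G=36, effect=0.0):
    profiles = []
    for i in range(n_subjects):
        base = 20 + 10 * np.sin(2 * np.pi * np.arange(G) / G) + rng.normal(0, 2, G)
        drug = np.clip(base + rng.normal(0, 2, G) + effect, 0, None)
        plac = np.clip(base + rng.normal(0, 2, G), 0, None)
        profiles.append(DailyProfile(f"s{i}", "drug", drug, 1))
        profiles.append(DailyProfile(f"s{i}", "placebo", plac, 1))
    return profiles


class TestPermutationTest:
    def test_exhaustive_enumeration_matches_forced_sampler(self, rng):
        """For 4 paired subjects the sampled permutation distribution,
        forced to visit all 16 assignments, equals exhaustive enumeration
        at every grid point."""
        profiles = _paired_profiles(rng, 4)
        res_ex = pointwise_permutation_test(
            profiles, method="exhaustive", n_perm=16, seed=0
        )
        assert res_ex.F_perm.shape[0] == 16

        labels = np.array([p.condition for p in profiles], object)
        subjects = np.array([p.subject_id for p in profiles], object)
        from actiflm.flm import curve_matrix

        V = curve_matrix(profiles, 36)
        seen: dict = {}
        s = 0
        while len(seen) < 16:
            lab = permute_labels(labels, subjects, "paired", rng=s)
            seen[tuple(lab)] = pointwise_F(V[lab == "drug"], V[lab != "drug"])
            s += 1
        sampled = np.sort(np.vstack(list(seen.values())), axis=0)
        exhaustive = np.sort(res_ex.F_perm, axis=0)
        assert np.allclose(sampled, exhaustive, rtol=1e-12, atol=1e-12)

    def test_p_curve_strict_counting_rule(self, rng):
        profiles = _paired_profiles(rng, 5, effect=30.0)
        res = pointwise_permutation_test(profiles, n_perm=99, seed=5)
        # p values live on the grid {0, 1/n, ..., 1}
        assert np.all(np.isin(np.round(res.p_curve * 99), np.arange(100)))
        # where F_obs beats every permutation, strict-greater counting gives 0
        beats_all = (res.F_perm < res.F_obs[None, :]).all(axis=0)
        assert np.all(res.p_curve[beats_all] == 0.0)

    def test_significance_mask_matches_critical_curve(self, rng):
        profiles = _paired_profiles(rng, 5, effect=5.0)
        res = pointwise_permutation_test(profiles, n_perm=200, seed=6)
        mask = np.zeros(len(res.grid), bool)
        for iv in res.significant_intervals:
            mask |= iv.to_mask(len(res.grid))
        assert np.array_equal(mask, res.F_obs > res.crit_curve)

    def test_group_relabeling_symmetry(self, rng):
        """Swapping which condition is called 'drug' leaves F_obs and the
        p-curve unchanged."""
        profiles = _paired_profiles(rng, 5, effect=3.0)
        swapped = [
            DailyProfile(p.subject_id,
                         "placebo" if p.condition == "drug" else "drug",
                         p.values, p.n_days)
            for p in profiles
        ]
        r1 = pointwise_permutation_test(profiles, n_perm=50, seed=7)
        r2 = pointwise_permutation_test(swapped, n_perm=50, seed=7)
        assert np.allclose(r1.F_obs, r2.F_obs)
        assert np.allclose(r1.p_curve, r2.p_curve)

    def test_low_n_perm_warns(self, rng):
        profiles = _paired_profiles(rng, 4)
        with pytest.warns(UserWarning, match="unstable"):
            pointwise_permutation_test(profiles, n_perm=10, alpha=0.05, seed=1)

    def test_determinism(self, rng):
        profiles = _paired_profiles(rng, 5, effect=2.0)
        r1 = pointwise_permutation_test(profiles, n_perm=100, seed=11)
        r2 = pointwise_permutation_test(profiles, n_perm=100, seed=11)
        assert np.array_equal(r1.F_perm, r2.F_perm)
        assert np.array_equal(r1.p_curve, r2.p_curve)

    def test_effect_monotonicity(self, rng):
        """A stronger injected shift never reduces the average fraction of
        significant points (checked over a few seeds)."""
        fracs = []
        for effect in (0.0, 4.0, 12.0):
            per_seed = []
            for s in range(3):
                profiles = _paired_profiles(
                    np.random.default_rng(100 + s), 8, effect=effect
                )
                res = pointwise_permutation_test(profiles, n_perm=150, seed=s)
                per_seed.append(res.fraction_significant)
            fracs.append(np.mean(per_seed))
        assert fracs[0] <= fracs[1] + 0.05
        assert fracs[1] <= fracs[2] + 0.05
        assert fracs[2] > fracs[0]


def _result_with_mask(mask, diff=None):
    G = len(mask)
    mask = np.asarray(mask, bool)
    F_obs = np.where(mask, 10.0, 0.1)
    crit = np.ones(G)
    mean_a = np.full(G, 2.0) if diff is None else 2.0 + np.asarray(diff, float)
    return FLMResult(
        grid=(np.arange(G) + 0.5) * 1440.0 / G,
        F_obs=F_obs,
        F_perm=np.zeros((1, G)),
        crit_curve=crit,
        p_curve=np.where(mask, 0.0, 0.9),
        alpha=0.05,
        n_perm=1,
        scheme="paired",
        seed=0,
        conditions=("drug", "placebo"),
        mean_curves={"drug": mean_a, "placebo": np.full(G, 2.0)},
    )


class TestIntervals:
    def test_no_significance_gives_empty_list(self):
        res = _result_with_mask(np.zeros(144, bool))
        assert extract_significant_intervals(res) == []

    def test_wrap_merge_across_midnight(self):
        """23:00-24:00 and 00:00-06:00 merge into one wrapped interval."""
        mask = np.zeros(144, bool)
        mask[138:] = True  # 23:00-24:00
        mask[:36] = True  # 00:00-06:00
        res = _result_with_mask(mask)
        ivs = extract_significant_intervals(res)
        assert len(ivs) == 1
        assert ivs[0].start_minute == 1380.0
        assert ivs[0].end_minute == 360.0
        assert ivs[0].length == 450.0 - 30.0  # 7 hours of cells

    def test_min_length_filters_singletons(self):
        mask = np.zeros(144, bool)
        mask[::2] = True  # alternating single cells (10 min each)
        res = _result_with_mask(mask)
        assert extract_significant_intervals(res, min_length=50) == []

    def test_direction_annotation(self):
        mask = np.zeros(144, bool)
        mask[10:20] = True
        diff = np.zeros(144)
        diff[10:20] = -1.0  # drug below placebo there
        res = _result_with_mask(mask, diff=diff)
        (iv,) = extract_significant_intervals(res)
        assert iv.direction == "placebo>drug"

    def test_full_circle(self):
        res = _result_with_mask(np.ones(144, bool))
        (iv,) = extract_significant_intervals(res)
        assert iv.length == 1440.0
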