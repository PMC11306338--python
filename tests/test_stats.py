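"""Tests of MAD rejection, cohort summaries, rank tests, and power."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mtgrowth import (
    InputError,
    RunFeatures,
    Trace,
    compare_groups,
    extract_features,
    mad_reject,
    mann_whitney_u,
    normality_battery,
    power_by_simulation,
    standard_error,
    summarize_cohort,
)


def _features(od=1.0, t10=20.0, b=2.2, run_id=""):
    return RunFeatures(od_final=od, t10=t10, t50=2 * t10, b=b, A=1e-3,
                       fit_n=20, fit_r2=0.99, run_id=run_id)


class TestMadReject:
    def test_hand_computed_example(self):
        # median 3, MAD 1: |100-3| / 1.4826 = 65.4 >> 3
        kept, rejected = mad_reject([1, 2, 3, 4, 100], k=3)
        assert list(kept) == [1.0, 2.0, 3.0, 4.0]
        assert list(rejected) == [4]

    def test_all_equal_values_kept(self):
        kept, rejected = mad_reject([5.0] * 10)
        assert kept.size == 10
        assert rejected.size == 0

    def test_zero_mad_rejects_only_off_median_values(self):
        kept, rejected = mad_reject([1.0, 1.0, 1.0, 1.0, 7.0])
        assert list(kept) == [1.0] * 4
        assert list(rejected) == [4]

    def test_normal_tail_rejection_fraction(self):
        # threshold 3 * 1.4826 * MAD -> 3 sigma in the large-sample limit,
        # so the rejection fraction approaches 2 * Phi(-3) = 0.0027
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100_000)
        _, rejected = mad_reject(x, k=3)
        frac = rejected.size / x.size
        assert 0.0020 < frac < 0.0035

    def test_idempotent_on_typical_input(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 50), [40.0]])
        kept1, _ = mad_reject(x)
        kept2, rejected2 = mad_reject(kept1)
        assert rejected2.size == 0
        assert np.array_equal(kept1, kept2)

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            mad_reject([1.0, 2.0])


class TestStandardError:
    def test_hand_computed_value(self):
        assert standard_error([1, 2, 3]) == pytest.approx(0.5774, abs=1e-4)

    def test_constant_list_gives_zero(self):
        assert standard_error([2.0] * 7) == 0.0

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2,
                    max_size=30))
    def test_equals_sample_sd_over_sqrt_n(self, values):
        arr = np.asarray(values)
        expected = np.std(arr, ddof=1) / math.sqrt(arr.size)
        assert standard_error(arr) == pytest.approx(expected, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(InputError):
            standard_error([1.0])


class TestSummarizeCohort:
    def test_identical_runs(self):
        feats = [_features(b=2.2) for _ in range(10)]
        summary = summarize_cohort(feats, dt_values=[0.8] * 10)
        assert summary.n == 10
        assert summary.b_mean == pytest.approx(2.2)
        assert summary.b_se == 0.0
        assert summary.dt_c == pytest.approx(0.8)

    def test_outlier_removed_and_summary_unbiased(self):
        rng = np.random.default_rng(8)
        b_clean = rng.normal(2.2, 0.1, 24)
        clean = [_features(b=v, run_id=f"r{i}") for i, v in enumerate(b_clean)]
        spiked = clean + [_features(b=22.0, run_id="outlier")]
        s_clean = summarize_cohort(clean)
        s_spiked = summarize_cohort(spiked)
        assert 24 not in set(s_spiked.kept_indices)  # the spiked run is gone
        assert abs(s_spiked.b_mean - s_clean.b_mean) < max(s_clean.b_se, 1e-6) * 3

    def test_reported_n_is_retained_count(self):
        feats = [_features(b=2.2 + 0.01 * i) for i in range(9)]
        feats.append(_features(b=50.0))
        summary = summarize_cohort(feats)
        assert summary.n_input == 10
        assert summary.n == 10 - summary.rejected_indices.size
        assert summary.n < 10

    def test_run_flagged_on_any_parameter_removed_everywhere(self):
        feats = [_features(od=1.0, t10=20.0, b=2.2) for _ in range(9)]
        feats.append(_features(od=1.0, t10=500.0, b=2.2))  # t10 outlier only
        summary = summarize_cohort(feats)
        assert summary.n == 9
        assert summary.t10_mean == pytest.approx(20.0)
        assert summary.b_mean == pytest.approx(2.2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            summarize_cohort([])


def _enumeration_p(x, y):
    """Brute-force exact two-sided Mann-Whitney p over all labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size

    def u_stat(xs, ys):
        return sum((xi > yi) for xi in xs for yi in ys)

    u_obs = u_stat(x, y)
    center = n * m / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        if abs(u_stat(xs, ys) - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_small_sample_exact_value(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p >= 0.99

    def test_exact_mode_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for n, m in [(2, 3), (3, 3), (4, 5), (5, 5), (6, 4)]:
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, m)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(_enumeration_p(x, y), abs=1e-12)

    @given(shift=st.floats(min_value=-2, max_value=2))
    def test_invariant_under_monotone_transform(self, shift):
        rng = np.random.default_rng(3)
        x = rng.normal(shift, 1, 12)
        y = rng.normal(0, 1, 15)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        _, p3 = mann_whitney_u(x ** 3, y ** 3)
        assert p2 == pytest.approx(p1, abs=1e-12)
        assert p3 == pytest.approx(p1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])


class TestCompareGroups:
    def test_identical_cohorts_show_no_differences(self):
        feats = [_features(od=1.0 + 0.01 * i, t10=20 + i, b=2.2 + 0.01 * i)
                 for i in range(10)]
        results = compare_groups(feats, list(feats))
        for r in results:
            assert r.p_measured > 0.9
            assert not r.significant_strict
            assert not r.significant_weak

    def test_separated_exponents_flagged_at_strict_threshold(self):
        rng = np.random.default_rng(17)
        flagged = 0
        reps = 20
        for _ in range(reps):
            a = [_features(b=v) for v in rng.normal(2.2, 0.2, 25)]
            b = [_features(b=v) for v in rng.normal(3.0, 0.2, 25)]
            res = {r.parameter: r for r in compare_groups(a, b)}
            flagged += res["b"].significant_strict
        assert flagged >= 0.95 * reps

    def test_time_scaled_copy_only_differs_before_stretching(self, avrami_trace):
        taus = [18.0, 20.0, 22.0, 24.0, 26.0, 28.0, 30.0, 32.0, 34.0, 36.0]
        group_a = [avrami_trace(tau=tau, dt=1.0, t_end=360.0) for tau in taus]
        group_b = [Trace(times=tr.times * 2.0, od=tr.od.copy()) for tr in group_a]
        feats_a = [extract_features(tr) for tr in group_a]
        feats_b = [extract_features(tr) for tr in group_b]
        res = {r.parameter: r for r in compare_groups(
            feats_a, feats_b, traces_a=group_a, traces_b=group_b)}
        assert res["t10"].p_measured < 1e-3       # measured t10 differs
        assert res["t10"].p_stretched > 0.05      # stretched t10 does not
        assert res["b"].p_measured > 0.9          # exponent is scale invariant


class TestNormalityBattery:
    def test_jarque_bera_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.gamma(2.0, 1.0, 150)
            report = normality_battery(x, lilliefors_sims=100)
            jb, p = report.jarque_bera
            jb_ref, p_ref = sps.jarque_bera(x)
            assert jb == pytest.approx(jb_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_anderson_darling_statistic_matches_scipy(self):
        import warnings

        rng = np.random.default_rng(9)
        x = rng.standard_normal(120)
        report = normality_battery(x, lilliefors_sims=100)
        a2_star, _ = report.anderson_darling
        n = x.size
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            a2_ref = sps.anderson(x, "norm").statistic
        expected = a2_ref * (1 + 0.75 / n + 2.25 / n**2)
        assert a2_star == pytest.approx(expected, abs=1e-9)

    def test_uniform_sample_fails_battery(self):
        rng = np.random.default_rng(2)
        report = normality_battery(rng.uniform(0, 1, 500), lilliefors_sims=2000)
        assert report.any_fail

    def test_normal_sample_passes_battery(self):
        rng = np.random.default_rng(3)
        report = normality_battery(rng.standard_normal(500), lilliefors_sims=2000)
        assert not report.any_fail

    def test_each_test_has_roughly_nominal_size(self):
        # rejection rate of each test under the null, over seeded replicates
        rng = np.random.default_rng(11)
        reps, n = 150, 60
        rejections = {"anderson_darling": 0, "kolmogorov_smirnov": 0,
                      "lilliefors": 0, "jarque_bera": 0}
        for i in range(reps):
            x = rng.standard_normal(n)
            report = normality_battery(x, lilliefors_sims=1500, seed=i)
            d = report.as_dict()
            for name in rejections:
                rejections[name] += d[name][1] < 0.05
        for name, count in rejections.items():
            # JB is conservative at moderate n; KS anti-conservative never
            assert 0.0 <= count / reps <= 0.12, name

    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            normality_battery(np.arange(5.0))


class TestPowerBySimulation:
    def test_null_case_power_near_alpha(self):
        power = power_by_simulation(2.0, 0.3, 2.0, 0.3, 25, n_sims=3000, seed=1)
        assert power == pytest.approx(0.05, abs=0.02)

    def test_saturated_case_power_near_one(self):
        power = power_by_simulation(0.0, 0.1, 1.0, 0.1, 25, n_sims=500, seed=1)
        assert power > 0.999

    def test_against_analytic_t_test_approximation(self):
        # two-sample t power with the 0.955 ARE of the rank test
        mean_a, sd_a, mean_b, sd_b, n = 2.98, 0.20, 2.91, 0.44, 200
        d = abs(mean_a - mean_b) / math.sqrt((sd_a**2 + sd_b**2) / 2.0)
        ncp = d * math.sqrt(0.955 * n / 2.0)
        analytic = sps.norm.sf(sps.norm.ppf(0.975) - ncp) \
            + sps.norm.cdf(-sps.norm.ppf(0.975) - ncp)
        mc = power_by_simulation(mean_a, sd_a, mean_b, sd_b, n, n_sims=2000, seed=2)
        assert mc == pytest.approx(analytic, abs=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            power_by_simulation(0, -1.0, 0, 1.0, 10)
        with pytest.raises(InputError):
            power_by_simulation(0, 1.0, 0, 1.0, 1)
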