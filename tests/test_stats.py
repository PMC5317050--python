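"""Population statistics: CV², calibrator normalization, cardinality
equalization, rank-sum comparison, fits, photobleach QC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellquant.stats import (
    SampleDistribution,
    assess_photobleaching,
    compare_distributions,
    cross_instrument_fit,
    equalize_cardinality,
    normalize_to_calibrator,
    population_stats,
    subgroup_stability,
)


def sample(values, sample_id="s", **kw):
    return SampleDistribution(sample_id=sample_id, values=np.asarray(values, float), **kw)


def lognormal(rng, n, mean, cv2):
    s2 = math.log1p(cv2)
    return rng.lognormal(math.log(mean) - s2 / 2, math.sqrt(s2), size=n)


# ---------------------------------------------------------------------------
# population_stats
# ---------------------------------------------------------------------------

class TestPopulationStats:
    def test_constant_values_have_zero_cv2(self):
        ps = population_stats([2.5] * 10)
        assert ps.sd == 0.0
        assert ps.cv2 == 0.0

    def test_small_sample_arithmetic(self):
        ps = population_stats([1.0, 2.0, 3.0])
        assert ps.mean == 2.0
        assert ps.sd == 1.0  # sample (n-1) SD
        assert ps.cv2 == 0.25

    def test_zero_mean_with_dispersion_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            population_stats([-1.0, 1.0])

    def test_needs_two_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            population_stats([1.0])

    def test_replicate_se_used_when_structure_present(self):
        values = np.concatenate([np.full(50, 1.0), np.full(50, 1.2), np.full(50, 0.8)])
        reps = np.repeat([1, 2, 3], 50)
        ps = population_stats(values, replicate_ids=reps)
        assert ps.se_method == "replicates"
        assert ps.se == pytest.approx(np.std([1.0, 1.2, 0.8], ddof=1) / math.sqrt(3))

    def test_cv2_recovery_on_lognormal_within_3_bootstrap_se(self, rng):
        target = 0.09
        v = lognormal(rng, 12_000, 0.5, target)
        boot = [
            population_stats(rng.choice(v, size=len(v), replace=True)).cv2
            for _ in range(200)
        ]
        se = np.std(boot, ddof=1)
        assert abs(population_stats(v).cv2 - target) < 3 * se

    @settings(max_examples=30, deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_cv2_scale_invariant(self, scale, seed):
        v = np.random.default_rng(seed).lognormal(0.0, 0.3, size=50)
        assert population_stats(v * scale).cv2 == pytest.approx(
            population_stats(v).cv2, rel=1e-9
        )


# ---------------------------------------------------------------------------
# calibrator normalization
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_calibrator_self_normalizes_to_unit_mean(self, rng):
        cal = sample(lognormal(rng, 500, 0.8, 0.09), "cal", is_calibrator=True)
        out = normalize_to_calibrator(cal, cal)
        assert np.mean(out.values) == pytest.approx(1.0, rel=1e-12)

    def test_half_mean_sample_normalizes_to_half(self):
        cal = sample([2.0, 2.0, 2.0, 2.0])
        s = sample([1.0, 1.0, 1.0, 1.0])
        assert np.mean(normalize_to_calibrator(s, cal).values) == pytest.approx(0.5)

    def test_nonpositive_calibrator_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            normalize_to_calibrator(sample([1.0, 2.0]), sample([0.0, 0.0]))

    def test_session_scale_factor_cancels(self, rng):
        """Two sessions differing by a global lamp-intensity factor give
        the same normalized dose response: the calibrator provides an
        implicit correction factor."""
        means = [0.1, 0.25, 0.5, 0.8]
        day1 = [sample(lognormal(rng, 3000, m, 0.09), f"c{i}") for i, m in enumerate(means)]
        day2 = [
            sample(1.3 * lognormal(rng, 3000, m, 0.09), f"c{i}")
            for i, m in enumerate(means)
        ]
        norm1 = [np.mean(normalize_to_calibrator(s, day1[-1]).values) for s in day1]
        norm2 = [np.mean(normalize_to_calibrator(s, day2[-1]).values) for s in day2]
        np.testing.assert_allclose(norm1, norm2, rtol=0.05)

    def test_cv2_unchanged_by_normalization(self, rng):
        cal = sample(lognormal(rng, 400, 0.9, 0.04), "cal")
        s = sample(lognormal(rng, 400, 0.3, 0.16), "s")
        before = population_stats(s).cv2
        after = population_stats(normalize_to_calibrator(s, cal)).cv2
        assert after == pytest.approx(before, rel=1e-12)


# ---------------------------------------------------------------------------
# cardinality equalization
# ---------------------------------------------------------------------------

class TestEqualize:
    def test_sample_at_target_returned_whole(self, rng):
        s = sample(rng.random(100))
        out = equalize_cardinality([s], 100, seed=1)
        np.testing.assert_array_equal(out[0].values, s.values)

    def test_deterministic_given_seed(self, rng):
        s = sample(rng.random(500))
        a = equalize_cardinality([s], 200, seed=7)[0]
        b = equalize_cardinality([s], 200, seed=7)[0]
        np.testing.assert_array_equal(a.values, b.values)

    def test_undersized_sample_named_in_error(self, rng):
        s = sample(rng.random(50), sample_id="tiny")
        with pytest.raises(ValueError, match="tiny"):
            equalize_cardinality([s], 100, seed=1)

    def test_subsample_mean_consistent_across_seeds(self, rng):
        """Across 100 seeds the subsampled mean stays within 3 standard
        errors of the full-sample mean (sampling without replacement)."""
        v = lognormal(rng, 5000, 0.5, 0.09)
        s = sample(v)
        full_mean = v.mean()
        n_sub = 1000
        # SE of the subsample mean includes the finite-population factor
        se = v.std(ddof=1) / math.sqrt(n_sub) * math.sqrt(1 - n_sub / len(v))
        devs = [
            abs(equalize_cardinality([s], n_sub, seed=k)[0].values.mean() - full_mean)
            for k in range(100)
        ]
        assert np.mean(np.asarray(devs) < 3 * se) > 0.95


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

class TestCompareDistributions:
    def test_identical_sequences_give_p_one(self):
        v = np.arange(1.0, 31.0)
        assert compare_distributions(v, v) == pytest.approx(1.0)

    def test_fully_separated_tiny_samples_match_exact_enumeration(self):
        """{1,2,3} vs {101,102,103}: U = 0; the exact two-sided p equals
        the tail probability enumerated over all C(6,3) rank assignments."""
        a, b = [1.0, 2.0, 3.0], [101.0, 102.0, 103.0]
        with pytest.warns(UserWarning):
            p = compare_distributions(a, b)
        # enumeration oracle: U statistic for every split of ranks 1..6
        ranks = set(range(1, 7))
        u_obs = 0  # all of a below all of b
        count_extreme = 0
        total = 0
        for combo in itertools.combinations(sorted(ranks), 3):
            u = sum(combo) - 3 * 4 / 2
            u = min(u, 9 - u)  # two-sided: either group equally extreme
            total += 1
            if u <= u_obs:
                count_extreme += 1
        assert p == pytest.approx(count_extreme / total)

    def test_shifted_populations_detected(self, rng):
        a = lognormal(rng, 400, 0.4, 0.09)
        b = lognormal(rng, 400, 0.55, 0.09)
        assert compare_distributions(a, b) < 0.01

    def test_null_pvalues_uniform(self, rng):
        """Under the null (same distribution) the p-values are uniform on
        (0,1): Kolmogorov–Smirnov check at the 1% level over 1000 reps."""
        from scipy import stats as sps

        pvals = []
        for _ in range(1000):
            a = rng.normal(0.0, 1.0, 40)
            b = rng.normal(0.0, 1.0, 40)
            pvals.append(compare_distributions(a, b))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

class TestCrossInstrumentFit:
    def test_exact_identity_line(self):
        x = np.array([0.1, 0.2, 0.4, 0.8, 1.0])
        fit = cross_instrument_fit(x, x, degree=1)
        assert fit.coefficients[1] == pytest.approx(1.0)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.mse == pytest.approx(0.0, abs=1e-24)

    def test_parabola_coefficients_recovered(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = 0.3 - 0.7 * x + 2.0 * x**2
        fit = cross_instrument_fit(x, y, degree=2)
        np.testing.assert_allclose(fit.coefficients, [0.3, -0.7, 2.0], atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            cross_instrument_fit([0.0, 1.0], [0.0, 1.0], degree=1)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cross_instrument_fit([1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0], degree=2)


# ---------------------------------------------------------------------------
# photobleaching report
# ---------------------------------------------------------------------------

class TestPhotobleach:
    def test_constant_series_passes_with_unit_ratio(self):
        rep = assess_photobleaching([5.0] * 15)
        assert rep.decay_ratio == 1.0
        assert rep.passed

    def test_twenty_percent_decay_fails(self):
        """A rate giving 20% total loss over 15 frames puts the
        closed-form first/last-third ratio below 0.95."""
        n = 15
        rate_dt = -math.log(0.8) / (n - 1)
        means = np.exp(-rate_dt * np.arange(n))
        k = n // 3
        expected = means[-k:].mean() / means[:k].mean()
        rep = assess_photobleaching(means)
        assert rep.decay_ratio == pytest.approx(expected, rel=1e-12)
        assert expected < 0.95
        assert not rep.passed

    def test_three_images_use_first_and_last(self):
        rep = assess_photobleaching([10.0, 7.0, 6.0])
        assert rep.mean_first_third == 10.0
        assert rep.mean_last_third == 6.0

    def test_threshold_boundary_inclusive(self):
        means = [1.0, 1.0, 0.95]
        rep = assess_photobleaching(means, threshold=0.95)
        assert rep.decay_ratio == pytest.approx(0.95)
        assert rep.passed


# ---------------------------------------------------------------------------
# subgroup stability
# ---------------------------------------------------------------------------

class TestSubgroupStability:
    def test_correlation_grows_with_group_size(self, rng):
        """Conditions differ in noise level (CV² falls with induction, as
        in an induction series), so the across-condition CV² profile is a
        real signal the subgroups estimate better and better."""
        means = [0.08, 0.2, 0.45, 0.7, 1.0]
        cv2s = [0.49, 0.25, 0.09, 0.04, 0.01]
        samples = [
            sample(lognormal(rng, 12_000, m, c), f"c{i}")
            for i, (m, c) in enumerate(zip(means, cv2s))
        ]
        corr = subgroup_stability(samples, [10, 100, 1000], statistic="cv2", seed=3)
        assert corr[10] <= corr[100] <= corr[1000]
        assert corr[1000] > 0.99

    def test_mean_statistic_stabilizes_quickly(self, rng):
        means = [0.1, 0.3, 0.6, 1.0]
        samples = [
            sample(lognormal(rng, 4000, m, 0.09), f"c{i}") for i, m in enumerate(means)
        ]
        corr = subgroup_stability(samples, [50, 500], statistic="mean", seed=4)
        assert corr[500] > 0.99
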