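"""Study-level statistics: summaries, Wilcoxon rank-sum test, pre/post
comparison and PM10 mass concentration."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from aerovol import (
    SizeDistribution,
    compare_pre_post,
    generate_study,
    measurement_summary,
    pm10_mass_concentration,
    study_truth_decay_rates,
    wilcoxon_rank_sum,
)
from aerovol.volatility import VolatilityResult


def _result(dv, cls="volatile"):
    kappa = 0.3
    return VolatilityResult(
        track_id=0, alpha_um3=dv / kappa, kappa_per_s=kappa, b_um3=0.0,
        tau_s=1 / kappa, v0_um3=dv / kappa, dv_tau_um3_per_s=dv,
        r_squared=0.99, assigned_class=cls, fit_converged=True,
    )


class TestMeasurementSummary:
    def test_mean_decay_rate(self, default_config):
        s = measurement_summary([_result(0.2), _result(0.4)], default_config)
        assert s.mean_dv_tau == pytest.approx(0.3)
        assert s.n_particles == 2

    def test_all_volatile_percentages(self, default_config):
        s = measurement_summary([_result(0.2)] * 4, default_config)
        assert s.pct_volatile == 100.0
        assert s.pct_volatile_plus_semi == 100.0

    def test_sampled_air_volume_is_13_litres(self, default_config):
        s = measurement_summary([_result(0.2)], default_config)
        assert s.sampled_air_volume_l == pytest.approx(13.0)

    def test_percentages_sum_to_100(self, default_config):
        results = ([_result(0.5, "volatile")] * 3
                   + [_result(0.2, "semi_volatile")] * 2
                   + [_result(0.01, "non_volatile")] * 5)
        s = measurement_summary(results, default_config)
        total = s.pct_volatile + s.pct_semi_volatile + s.pct_non_volatile
        assert total == pytest.approx(100.0)

    def test_empty_measurement_marked_undefined(self, default_config):
        s = measurement_summary([], default_config)
        assert s.n_particles == 0
        assert math.isnan(s.mean_dv_tau)


class TestWilcoxonRankSum:
    def test_separated_samples_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_two_sided_symmetry(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(1.0, size=5)
        _, p_xy = wilcoxon_rank_sum(x, y)
        _, p_yx = wilcoxon_rank_sum(y, x)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_exact_matches_scipy_for_untied_data(self, rng):
        """For every sample-size split with n_x + n_y <= 10, the exact p
        equals scipy's exact Mann-Whitney p (tie-free data)."""
        for n_x, n_y in [(a, b) for a in range(1, 10) for b in range(1, 10)
                         if a + b <= 10]:
            pooled = rng.permutation(np.arange(1.0, n_x + n_y + 1))
            x, y = pooled[:n_x], pooled[n_x:]
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            p_ref = mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12), (n_x, n_y)

    def test_exact_handles_ties_with_midranks(self):
        """x = {1,1}, y = {2,2}: midranks (1.5, 1.5, 3.5, 3.5); of the six
        assignments the rank sums are {3,5,5,5,5,7}, so the two-sided p of
        the observed W = 3 is 2/6."""
        w, p = wilcoxon_rank_sum([1.0, 1.0], [2.0, 2.0], mode="exact")
        assert w == 3.0
        assert p == pytest.approx(2.0 / 6.0)

    def test_normal_mode_close_to_exact_at_moderate_n(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(0.5, size=6)
        _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
        _, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
        assert p_norm == pytest.approx(p_exact, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestComparePrePost:
    def test_single_value_strata_cannot_reject(self):
        report = compare_pre_post([False, True], [[0.1], [0.9]])
        assert report.p_value == 1.0

    def test_missing_stratum_rejected(self):
        with pytest.raises(ValueError):
            compare_pre_post([True, True], [[0.1], [0.2]])

    def test_direction_and_medians(self, rng):
        pre = [list(rng.uniform(0.1, 0.3, size=50))]
        post = [list(rng.uniform(0.4, 0.8, size=50))]
        report = compare_pre_post([False, True], pre + post)
        assert report.post_higher
        assert report.median_post > report.median_pre
        assert report.p_value < 0.001

    def test_measurement_level_pooling(self, rng):
        flags = [False, False, True, True]
        dv = [list(rng.uniform(0.1, 0.2, 30)) for _ in range(2)] + [
            list(rng.uniform(0.3, 0.5, 30)) for _ in range(2)
        ]
        report = compare_pre_post(flags, dv, level="measurement")
        assert report.n_pre == 2 and report.n_post == 2

    def test_study_truth_pipeline(self, stats_config):
        schedule = [False] * 3 + [True] * 3
        study = generate_study(stats_config, 6, schedule, effect_size=0.8,
                               n_particles_per_measurement=60)
        flags, rates = study_truth_decay_rates(study, stats_config)
        report = compare_pre_post(flags, rates)
        assert report.n_pre == 180 and report.n_post == 180
        assert report.post_higher


class TestPM10:
    def test_single_bin_unit_diameter(self):
        """10^6 particles/m^3 at d = 1 um and rho = 1.1 g/cm^3 carry
        (pi/6) * 1.1e-6 ug each, i.e. 0.576 ug/m^3."""
        dist = SizeDistribution(np.array([0.9, 10.0 / 9.0]),
                                np.array([1e6]), 1.0)
        c = pm10_mass_concentration(dist, 1.1)
        assert c == pytest.approx(math.pi / 6.0 * 1.1, rel=1e-9)
        assert c == pytest.approx(0.576, abs=1e-3)

    def test_bins_above_10um_excluded(self):
        dist = SizeDistribution(np.array([14.0, 16.0]), np.array([1e6]), 1.0)
        assert pm10_mass_concentration(dist) == 0.0

    def test_empty_distribution(self):
        dist = SizeDistribution(np.array([1.0, 2.0]), np.array([0.0]), 1.0)
        assert pm10_mass_concentration(dist) == 0.0

    def test_mass_cubic_in_diameter(self):
        small = SizeDistribution(np.array([1.0, 1.21]), np.array([500.0]), 2.0)
        big = SizeDistribution(np.array([2.0, 2.42]), np.array([500.0]), 2.0)
        ratio = pm10_mass_concentration(big) / pm10_mass_concentration(small)
        assert ratio == pytest.approx(8.0, rel=1e-9)

    def test_mass_linear_in_counts(self):
        d1 = SizeDistribution(np.array([1.0, 2.0]), np.array([100.0]), 1.0)
        d2 = SizeDistribution(np.array([1.0, 2.0]), np.array([300.0]), 1.0)
        assert pm10_mass_concentration(d2) == pytest.approx(
            3 * pm10_mass_concentration(d1)
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            SizeDistribution(np.array([2.0, 1.0]), np.array([1.0]), 1.0)
        with pytest.raises(ValueError):
            SizeDistribution(np.array([0.1, 1.0]), np.array([1.0]), 1.0)
        dist = SizeDistribution(np.array([1.0, 2.0]), np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            pm10_mass_concentration(dist)
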