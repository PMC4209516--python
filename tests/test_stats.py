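"""SNR estimation, Monte Carlo error propagation, and group statistics."""

import numpy as np
import pytest

from relaxovb.exchange import VoxelRelaxationSeries, r1e_no_exchange, r1t_two_site
from relaxovb.mprage import mprage_signal
from relaxovb.stats import (
    estimate_snr,
    monte_carlo_r1,
    monte_carlo_vb,
    outlier_flags,
    paired_tests_modified_bonferroni,
    regression_r2,
    water_fraction_ratio,
    within_subject_anova,
)
from relaxovb.volumes import VolumeMap

from conftest import make_blood_curve


def _snr_volumes(signal=100.0, noise_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.zeros((20, 20, 20))
    fg = np.zeros_like(vals, dtype=bool)
    fg[5:15, 5:15, 5:15] = True
    vals[fg] = signal
    vals += rng.normal(0, noise_sd, vals.shape)
    bg = np.zeros_like(fg)
    bg[:3] = True
    return (VolumeMap(vals, (1, 1, 1)), VolumeMap(fg, (1, 1, 1)),
            VolumeMap(bg, (1, 1, 1)))


class TestSnr:
    def test_known_noise_construction(self):
        vol, fg, bg = _snr_volumes(100.0, 1.0)
        assert estimate_snr(vol, fg, bg) == pytest.approx(100.0, rel=0.05)

    def test_doubling_signal_doubles_snr(self):
        vol1, fg, bg = _snr_volumes(100.0, 1.0, seed=1)
        vol2, _, _ = _snr_volumes(200.0, 1.0, seed=1)
        r = estimate_snr(vol2, fg, bg) / estimate_snr(vol1, fg, bg)
        assert r == pytest.approx(2.0, rel=1e-3)

    def test_noise_free_volume_rejected(self):
        vals = np.zeros((10, 10, 10))
        vals[5:] = 50.0
        fg = VolumeMap(vals > 0, (1, 1, 1))
        bg = VolumeMap(vals == 0, (1, 1, 1))
        with pytest.raises(ValueError):
            estimate_snr(VolumeMap(vals, (1, 1, 1)), fg, bg)

    def test_small_background_rejected(self):
        vol, fg, _ = _snr_volumes()
        tiny = np.zeros((20, 20, 20), dtype=bool)
        tiny[0, 0, :5] = True
        with pytest.raises(ValueError):
            estimate_snr(vol, fg, VolumeMap(tiny, (1, 1, 1)))


class TestMonteCarloR1:
    def _wmh_signals(self, protocol, t1_ms=1608.0):
        return np.array([abs(mprage_signal(1e3 / t1_ms, 800.0, protocol, ti))
                         for ti in protocol.ti_list])

    def test_variance_vanishes_at_high_snr(self, protocol):
        sig = self._wmh_signals(protocol)
        hi = monte_carlo_r1(sig, protocol, snr=1e7, n=200, seed=0)
        assert hi.relative_variance_pct < 1e-8

    def test_wmh_voxel_at_snr100_below_published_bound(self, protocol):
        sig = self._wmh_signals(protocol)
        rep = monte_carlo_r1(sig, protocol, snr=100.0, n=1000, seed=0)
        assert rep.relative_variance_pct < 0.04

    def test_monotone_nonincreasing_in_snr(self, protocol):
        sig = self._wmh_signals(protocol)
        rvs = [monte_carlo_r1(sig, protocol, snr=s, n=400, seed=3
                              ).relative_variance_pct
               for s in (50.0, 100.0, 400.0)]
        assert rvs[0] > rvs[1] > rvs[2]

    def test_deterministic_under_fixed_seed(self, protocol):
        sig = self._wmh_signals(protocol)
        a = monte_carlo_r1(sig, protocol, 100.0, n=200, seed=9)
        b = monte_carlo_r1(sig, protocol, 100.0, n=200, seed=9)
        assert a.relative_variance_pct == b.relative_variance_pct


class TestMonteCarloVb:
    def _series(self, curve, vb=0.018, r1t0=1e3 / 1608.0):
        r1e = r1e_no_exchange(r1t0, curve.r1b0, vb)
        return VoxelRelaxationSeries(r1t0,
                                     r1t_two_site(curve.r1b_values, r1e, vb))

    def test_zero_sd_gives_zero_variance(self):
        curve = make_blood_curve()
        rep = monte_carlo_vb(self._series(curve), curve, 0.0, n=200, seed=0)
        assert rep.relative_variance_pct == pytest.approx(0.0, abs=1e-12)

    def test_default_voxel_within_published_bound(self):
        curve = make_blood_curve()
        rep = monte_carlo_vb(self._series(curve), curve, 0.004, n=1000, seed=0)
        assert rep.relative_variance_pct <= 2.0

    def test_variance_scales_quadratically_with_sd(self):
        curve = make_blood_curve()
        lo = monte_carlo_vb(self._series(curve), curve, 0.002, n=800, seed=5)
        hi = monte_carlo_vb(self._series(curve), curve, 0.004, n=800, seed=5)
        ratio = hi.relative_variance_pct / lo.relative_variance_pct
        assert ratio == pytest.approx(4.0, abs=1.0)

    def test_gaussian_option_runs(self):
        curve = make_blood_curve()
        rep = monte_carlo_vb(self._series(curve), curve, 0.003, n=200, seed=1,
                             distribution="gaussian")
        assert rep.relative_variance_pct > 0


class TestWithinSubjectAnova:
    def test_identical_condition_means_give_zero_f(self):
        y = np.tile(np.array([[1.0, 1.0, 1.0]]), (5, 1))
        y += np.arange(5)[:, None]  # subject offsets only
        f, df, p = within_subject_anova(y)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert df == (2, 8)

    def test_hand_worked_textbook_dataset(self):
        # 5 subjects x 3 conditions; partitioned sums of squares by hand
        y = np.array([
            [8.0, 7.0, 6.0],
            [9.0, 8.0, 5.0],
            [6.0, 5.0, 3.0],
            [8.0, 6.0, 4.0],
            [7.0, 5.0, 2.0],
        ])
        grand = y.mean()
        ss_cond = 5 * np.sum((y.mean(axis=0) - grand) ** 2)
        ss_subj = 3 * np.sum((y.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((y - grand) ** 2) - ss_cond - ss_subj
        f_hand = (ss_cond / 2) / (ss_err / 8)
        f, df, p = within_subject_anova(y)
        assert f == pytest.approx(f_hand, rel=1e-12)
        assert 0 < p < 1

    def test_matches_independent_implementation(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
        f, (df1, df2), p = within_subject_anova(y)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "cond": np.tile(np.arange(3), 8),
            "y": y.ravel(),
        })
        res = pg.rm_anova(data=df, dv="y", within="cond", subject="subject")
        assert f == pytest.approx(float(res["F"][0]), rel=1e-9)
        assert p == pytest.approx(float(res["p_unc"][0]), rel=1e-9)

    def test_invariant_to_per_subject_constant(self):
        rng = np.random.default_rng(4)
        y = rng.normal(2.0, 0.5, (6, 3))
        f1, _, _ = within_subject_anova(y)
        f2, _, _ = within_subject_anova(y + rng.normal(0, 10, (6, 1)))
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(0, 1, (6, 3)) + rng.normal(0, 1, (6, 1))
            _, _, p = within_subject_anova(y)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            within_subject_anova(np.ones((2, 3)))


class TestModifiedBonferroni:
    def test_identical_pairs_not_significant(self):
        a = np.arange(10, dtype=float)
        res = paired_tests_modified_bonferroni([("x", a, a), ("y", a, a + 1)])
        assert res[0]["t"] == 0.0 and not res[0]["significant"]

    def test_stepup_pattern_matches_published_decisions(self):
        # raw p = {0.0001, 0.033, 0.9}: only the smallest survives at
        # familywise alpha 0.05 under the step-up adjustment
        rng = np.random.default_rng(0)
        pvals_target = [0.0001, 0.033, 0.9]
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals_target, alpha=0.05,
                                        method="simes-hochberg")
        assert list(reject) == [True, False, False]

    def test_decisions_use_adjusted_levels(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 40)
        pairs = [
            ("big", base, base + 2.0 + rng.normal(0, 0.5, 40)),
            ("weak", base, base + 0.4 + rng.normal(0, 1.0, 40)),
            ("null", base, base + rng.normal(0, 1.0, 40)),
        ]
        res = paired_tests_modified_bonferroni(pairs)
        assert res[0]["significant"]
        by_name = {r["name"]: r for r in res}
        assert by_name["null"]["p_raw"] > 0.001

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(77)
        n_sim, fwer = 2000, 0
        for _ in range(n_sim):
            a = rng.normal(0, 1, (3, 12))
            b = rng.normal(0, 1, (3, 12))
            res = paired_tests_modified_bonferroni(
                [(a[i], b[i]) for i in range(3)])
            fwer += any(r["significant"] for r in res)
        assert fwer / n_sim <= 0.05 + 0.01

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_tests_modified_bonferroni(
                [(np.ones(5), np.ones(4)), (np.ones(5), np.ones(5))])


class TestRegression:
    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        slope, r2, p = regression_r2(x, 3.0 * x - 1.0)
        assert slope == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)

    def test_null_expectation_of_r2(self):
        rng = np.random.default_rng(0)
        n = 18
        r2s = [regression_r2(rng.normal(size=n), rng.normal(size=n))[1]
               for _ in range(2000)]
        assert np.mean(r2s) == pytest.approx(1.0 / (n - 1), abs=0.01)

    def test_negative_association_sign(self):
        rng = np.random.default_rng(2)
        ventricle_volume = rng.uniform(3.0, 10.0, 18)
        vb = 3.0 - 0.15 * ventricle_volume + rng.normal(0, 0.2, 18)
        slope, r2, p = regression_r2(ventricle_volume, vb)
        assert slope < 0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            regression_r2(np.ones(5), np.arange(5.0))


class TestOutliers:
    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 2))
        X[7] = [10.0, -10.0]  # 10-SD displacement
        flags = outlier_flags(X)
        assert flags["flagged"][7]

    def test_homogeneous_cloud_low_flag_rate_by_mahalanobis(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (400, 2))
        flags = outlier_flags(X)
        assert flags["mahalanobis"].mean() <= 0.05

    def test_duplicated_rows_get_identical_flags(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (30, 2))
        X2 = np.vstack([X, X])
        flags = outlier_flags(X2)
        np.testing.assert_array_equal(flags["flagged"][:30], flags["flagged"][30:])

    def test_singular_covariance_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = X[:, 0]
        with pytest.raises(ValueError):
            outlier_flags(X)


class TestWaterFraction:
    def test_equal_t1_gives_zero(self):
        assert water_fraction_ratio(1500.0, 1500.0) == 0.0

    def test_published_lesion_comparisons(self):
        # pWMH vs dWMH: ~15%; WMH vs NAWM range: ~10.6% and ~28%
        assert water_fraction_ratio(1861.0, 1608.0) == pytest.approx(15.7, abs=0.1)
        assert water_fraction_ratio(1861.0, 1454.0) == pytest.approx(28.0, abs=0.1)
        assert water_fraction_ratio(1608.0, 1454.0) == pytest.approx(10.6, abs=0.1)

    def test_positive_t1_required(self):
        with pytest.raises(ValueError):
            water_fraction_ratio(-1.0, 1500.0)
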