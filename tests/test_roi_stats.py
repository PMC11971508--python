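"""Weighted ROI statistics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from livert1.roi_stats import (RoiSample, b1_sensitivity, circular_roi_pixels,
                               extract_rois, frame_to_samples, inaccuracy,
                               repeatability, roi_level_homogeneity,
                               samples_to_frame, weighted_subject_summary)


# -- independent brute-force evaluation of the printed estimators -----------

def brute_subject_summary(samples):
    num = den = 0.0
    for s in samples:
        w = s.n_pixels / np.var(s.pixel_t1s, ddof=1)
        for p in s.pixel_t1s:
            num += w * p
        den += s.n_pixels * w
    mu = num / den
    var = 0.0
    for s in samples:
        w = s.n_pixels / np.var(s.pixel_t1s, ddof=1)
        for p in s.pixel_t1s:
            var += w * (p - mu) ** 2
    return mu, np.sqrt(var / den)


def brute_roi_homogeneity(samples):
    mu, _ = brute_subject_summary(samples)
    num = den = 0.0
    for s in samples:
        w = s.n_pixels / np.var(s.pixel_t1s, ddof=1)
        num += w * (np.mean(s.pixel_t1s) - mu) ** 2
        den += w
    return np.sqrt(num / den)


def _random_samples(rng, n_slices=3, n_rois=3, n_pix=30):
    out = []
    for s in range(n_slices):
        for r in range(n_rois):
            out.append(RoiSample("s1", "r1", s, r,
                                 rng.normal(900 + 30 * r, 20 + 5 * s, n_pix)))
    return out


class TestWeightedSummary:
    def test_identical_pixels_give_value_and_zero_sd(self):
        samples = [RoiSample("s", "r", 0, i, np.full(10, 850.0) + [0, 1e-9][0])
                   for i in range(3)]
        # identical values -> zero SD weights get capped; mean unaffected
        with pytest.warns(UserWarning):
            mu, sd = weighted_subject_summary(samples)
        assert mu == pytest.approx(850.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_equal_weights_equal_sizes_give_pixel_mean(self, rng):
        a = rng.normal(900, 10, 20)
        b = a + 100.0  # same variance, shifted mean
        samples = [RoiSample("s", "r", 0, 0, a), RoiSample("s", "r", 0, 1, b)]
        mu, _ = weighted_subject_summary(samples)
        assert mu == pytest.approx(np.concatenate([a, b]).mean(), rel=1e-12)

    def test_matches_brute_force_on_random_fixture(self, rng):
        samples = _random_samples(rng)
        mu, sd = weighted_subject_summary(samples)
        bmu, bsd = brute_subject_summary(samples)
        assert mu == pytest.approx(bmu, rel=1e-12)
        assert sd == pytest.approx(bsd, rel=1e-12)

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            weighted_subject_summary([])


class TestRoiHomogeneity:
    def test_equal_roi_means_give_zero(self, rng):
        noise = rng.normal(0, 5, 12)
        noise -= noise.mean()
        samples = [RoiSample("s", "r", 0, i, 900.0 + noise) for i in range(3)]
        assert roi_level_homogeneity(samples) == pytest.approx(0.0, abs=1e-9)

    def test_two_rois_means_900_910_give_5(self):
        # equal sizes and SDs -> equal weights; dispersion = 5 ms exactly
        a = 900.0 + np.array([-1.0, 1.0])
        b = 910.0 + np.array([-1.0, 1.0])
        samples = [RoiSample("s", "r", 0, 0, a), RoiSample("s", "r", 0, 1, b)]
        assert roi_level_homogeneity(samples) == pytest.approx(5.0, rel=1e-12)

    def test_matches_brute_force(self, rng):
        samples = _random_samples(rng)
        assert roi_level_homogeneity(samples) == pytest.approx(
            brute_roi_homogeneity(samples), rel=1e-12)

    def test_single_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_level_homogeneity([RoiSample("s", "r", 0, 0, np.ones(5))])


class TestInaccuracy:
    def test_identical_gives_zero(self):
        assert inaccuracy([900.0, 950.0], [900.0, 950.0]) == 0.0

    def test_single_pair_definition(self):
        assert inaccuracy([950.0], [1000.0]) == pytest.approx(-0.05)

    def test_matches_brute_force_mean_of_ratios(self, rng):
        v = rng.uniform(700, 1100, 20)
        r = rng.uniform(700, 1100, 20)
        expect = np.mean([(a - b) / b for a, b in zip(v, r)])
        assert inaccuracy(v, r) == pytest.approx(expect, rel=1e-12)

    def test_missing_pairs_skipped(self):
        # mirrors reference maps missing for some volunteer/run combinations
        vfa = {("v1", "r1"): 900.0, ("v1", "r2"): 910.0, ("v2", "r1"): 950.0}
        ref = {("v1", "r1"): 1000.0, ("v2", "r1"): 1000.0}
        assert inaccuracy(vfa, ref) == pytest.approx(
            ((900 - 1000) / 1000 + (950 - 1000) / 1000) / 2)


class TestB1Sensitivity:
    def test_flat_t1_gives_zero_slope(self, rng):
        b1 = rng.uniform(0.7, 1.1, 12)
        res = b1_sensitivity(np.full(12, 900.0), b1)
        assert res.slope == pytest.approx(0.0, abs=1e-9)
        assert res.delta_t1_b1 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_exact_line_gives_exact_delta(self):
        b1 = np.array([0.8, 0.85, 0.9, 0.95, 1.0])
        t1 = 500.0 + 400.0 * b1
        res = b1_sensitivity(t1, b1, b1_range=0.2)
        assert res.delta_t1_b1 == pytest.approx(80.0, rel=1e-10)
        assert res.ci95[1] - res.ci95[0] == pytest.approx(0.0, abs=1e-6)
        assert res.p_value < 1e-10

    def test_ci_coverage_near_95_percent(self):
        rng = np.random.default_rng(7)
        b1 = np.linspace(0.7, 1.1, 15)
        slope_true, sigma = 300.0, 25.0
        hits = 0
        n_trials = 1000
        for _ in range(n_trials):
            t1 = 700.0 + slope_true * b1 + rng.normal(0, sigma, b1.size)
            res = b1_sensitivity(t1, b1)
            lo, hi = res.ci95
            if lo <= slope_true * res.delta_b1 <= hi:
                hits += 1
        assert hits / n_trials == pytest.approx(0.95, abs=0.025)

    def test_zero_b1_variance_rejected(self):
        with pytest.raises(ValueError):
            b1_sensitivity([900.0, 910.0, 920.0], [0.9, 0.9, 0.9])

    def test_dof_switch_widens_ci(self):
        rng = np.random.default_rng(3)
        b1 = np.linspace(0.7, 1.1, 10)
        t1 = 700.0 + 300.0 * b1 + rng.normal(0, 20, 10)
        narrow = b1_sensitivity(t1, b1)              # N-2 = 8 d.o.f.
        wide = b1_sensitivity(t1, b1, dof=2)         # printed variant
        assert (wide.ci95[1] - wide.ci95[0]) > (narrow.ci95[1] - narrow.ci95[0])


class TestRepeatability:
    def test_identical_runs_give_zero(self):
        a = np.array([900.0, 950.0, 1000.0, 870.0])
        res = repeatability(a, a.copy())
        assert res.sigma_within == 0.0
        assert res.rc == 0.0
        assert res.bland_altman_bias == 0.0

    def test_rc_is_196_sqrt2_sigma(self):
        # construct runs with known within-subject SD of 10 ms
        base = np.array([800.0, 900.0, 1000.0, 1100.0, 1200.0])
        d = 10.0 * np.sqrt(2.0)
        res = repeatability(base + d / 2, base - d / 2)
        assert res.sigma_within == pytest.approx(10.0, rel=1e-12)
        assert res.rc == pytest.approx(27.72, abs=0.01)

    def test_anova_residual_ms_equals_half_mean_square_diff(self, rng):
        a = rng.normal(950, 90, 10)
        b = a + rng.normal(0, 25, 10)
        res = repeatability(a, b)
        assert res.sigma_within ** 2 == pytest.approx(
            0.5 * np.mean((a - b) ** 2), rel=1e-12)

    def test_bland_altman_bias_is_mean_difference(self, rng):
        a = rng.normal(950, 90, 8)
        b = rng.normal(950, 90, 8)
        res = repeatability(a, b)
        assert res.bland_altman_bias == pytest.approx((a - b).mean(), rel=1e-12)
        assert res.bland_altman_loa == pytest.approx(
            1.96 * (a - b).std(ddof=1), rel=1e-12)

    def test_rc_scales_linearly_with_sigma(self, rng):
        base = rng.normal(950, 90, 10)
        noise = rng.normal(0, 1, 10)
        rc1 = repeatability(base + 10 * noise, base - 10 * noise).rc
        rc3 = repeatability(base + 30 * noise, base - 30 * noise).rc
        assert rc3 == pytest.approx(3 * rc1, rel=1e-12)

    def test_monte_carlo_recovers_design_rc(self):
        # 10 subjects, between-SD 90 ms, within-SD 21 ms: RC -> 58.2 ms
        rng = np.random.default_rng(11)
        rcs = []
        for _ in range(500):
            subj = rng.normal(950.0, 90.0, 10)
            a = subj + rng.normal(0, 21.0, 10)
            b = subj + rng.normal(0, 21.0, 10)
            rcs.append(repeatability(a, b).rc)
        assert np.median(rcs) == pytest.approx(1.96 * np.sqrt(2) * 21.0,
                                               rel=0.10)

    def test_paired_ci_against_scipy_interval(self, rng):
        a = rng.normal(950, 90, 10)
        b = a + rng.normal(5, 20, 10)
        res = repeatability(a, b)
        d = a - b
        lo, hi = sps.t.interval(0.95, 9, loc=d.mean(),
                                scale=d.std(ddof=1) / np.sqrt(10))
        assert res.mean_diff_ci95 == pytest.approx((lo, hi), rel=1e-12)

    def test_unequal_subject_sets_rejected(self):
        with pytest.raises(ValueError):
            repeatability([1.0, 2.0, 3.0], [1.0, 2.0])


class TestRoiExtraction:
    def test_circular_roi_radius(self):
        arr = np.ones((21, 21))
        vals = circular_roi_pixels(arr, (10, 10), 4)
        assert vals.size == np.sum(
            (np.arange(21)[:, None] - 10) ** 2
            + (np.arange(21)[None, :] - 10) ** 2 <= 16)

    def test_extract_and_frame_round_trip(self, rng):
        vol = rng.normal(900, 30, (32, 32, 3))
        centers = [(0, 10, 10), (0, 20, 20), (1, 16, 16)]
        samples = extract_rois(vol, centers, 4)
        df = samples_to_frame(samples)
        back = frame_to_samples(df)
        assert len(back) == len(samples)
        got = {(s.slice_id, s.roi_id): np.sort(s.pixel_t1s) for s in back}
        for s in samples:
            assert np.allclose(got[(s.slice_id, s.roi_id)],
                               np.sort(s.pixel_t1s))
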