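"""Unit and property tests for the variance-component statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpcrvar.variance import (
    RegressionResult,
    VarianceComponents,
    bias_corrected_sd,
    bootstrap_sd_ci,
    c4,
    fit_sd_vs_level,
    geometric_sd,
    inter_plate_sd,
    plate_estimates,
    pooled_inter_plate_sd,
    pooled_intra_sd,
    severe_outlier_filter,
    spearman_sd_vs_cq,
)
from qpcrvar.exceptions import ConfigurationError
from qpcrvar.simulate import inject_outliers

import pandas as pd
from scipy import stats


class TestSevereOutlierFilter:
    def test_degenerate_iqr_flags_any_deviation(self):
        res = severe_outlier_filter([5, 5, 5, 5, 100])
        assert list(res.removed) == [100]
        assert res.n_removed == 1

    def test_uniform_spread_keeps_everything(self):
        # 1..11: Q1=3.5, Q3=8.5, fences -11.5 / 23.5 lie outside the range
        res = severe_outlier_filter(np.arange(1, 12))
        assert res.n_removed == 0

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            res = severe_outlier_filter([1.0, 2.0, 100.0])
        assert res.n_removed == 0

    def test_single_pass_idempotent_on_unimodal_data(self, rng):
        values = rng.normal(50, 3, size=500)
        values[:5] += 40  # gross contamination
        first = severe_outlier_filter(values)
        second = severe_outlier_filter(first.kept)
        assert second.n_removed == 0

    def test_recovers_injected_gross_errors(self, rng):
        clean = rng.normal(50, 2, size=2352)
        iqr = float(np.diff(np.quantile(clean, [0.25, 0.75]))[0])
        contaminated, mask = inject_outliers(clean, 0.02, 12 * iqr, seed=rng)
        res = severe_outlier_filter(contaminated)
        # all injected points flagged; false positives essentially absent
        assert np.all(res.mask_removed[mask])
        assert res.n_removed <= mask.sum() + 3


class TestBiasCorrection:
    def test_c4_small_n_closed_forms(self):
        assert c4(2) == pytest.approx(math.sqrt(2 / math.pi), abs=1e-12)
        # independent Gamma-function evaluation
        n = 5
        direct = math.sqrt(2 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)
        assert c4(n) == pytest.approx(direct, abs=1e-14)

    def test_c4_asymptotic_limit(self):
        assert c4(10**6) == pytest.approx(1.0, abs=1e-6)

    def test_c4_rejects_degenerate_n(self):
        with pytest.raises(ValueError):
            c4(1)

    def test_two_point_sample(self):
        # sd([0,2], ddof=1) = sqrt(2); / c4(2) = sqrt(2)/sqrt(2/pi) = sqrt(pi)
        assert bias_corrected_sd([0, 2]) == pytest.approx(math.sqrt(math.pi), abs=1e-6)

    def test_constant_vector(self):
        assert bias_corrected_sd([3.3] * 10) == 0.0

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_never_below_sample_sd(self, values):
        arr = np.asarray(values)
        assert bias_corrected_sd(arr) >= np.std(arr, ddof=1) - 1e-12


class TestBootstrapCI:
    def test_constant_vector_gives_degenerate_ci(self):
        sd, (lo, hi) = bootstrap_sd_ci([2.0] * 12, B=1000, seed=1)
        assert sd == 0.0 and lo == 0.0 and hi == 0.0

    def test_deterministic_under_seed(self, rng):
        values = rng.normal(size=30)
        a = bootstrap_sd_ci(values, B=2000, seed=42)
        b = bootstrap_sd_ci(values, B=2000, seed=42)
        assert a == b

    def test_refuses_small_B(self, rng):
        with pytest.raises(ConfigurationError):
            bootstrap_sd_ci(rng.normal(size=20), B=500, seed=0)

    def test_ci_brackets_point_estimate(self, rng):
        values = rng.normal(0, 1, size=84)
        sd, (lo, hi) = bootstrap_sd_ci(values, B=2000, seed=3)
        assert lo <= sd <= hi


class TestPlateEstimates:
    def test_single_plate_mean(self):
        df = pd.DataFrame({"plate_id": "P1", "value": [1.0, 2.0, 3.0]})
        est = plate_estimates(df)
        assert est.loc["P1", "mean"] == pytest.approx(2.0)
        assert est.loc["P1", "k"] == 3

    def test_zero_noise_plates_have_zero_sd(self, noiseless_deletion_design):
        from qpcrvar.simulate import simulate_deletion_measurements

        df = simulate_deletion_measurements(noiseless_deletion_design)
        sub = df[df["sample_id"] == "A"]
        est = plate_estimates(sub)
        assert np.allclose(est["sd"], 0.0)

    def test_underfilled_plate_excluded(self):
        df = pd.DataFrame(
            {"plate_id": ["P1"] * 3 + ["P2"], "value": [1.0, 2.0, 3.0, 9.0]}
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            est = plate_estimates(df)
        assert list(est.index) == ["P1"]

    def test_pooled_sd_recovers_truth(self):
        # 200 replicate 3x24 experiments; pooled intra SD unbiased near truth
        rng = np.random.default_rng(5)
        sigma = 3.0
        pooled = []
        for _ in range(200):
            df = pd.DataFrame({
                "plate_id": np.repeat(["P1", "P2", "P3"], 24),
                "value": rng.normal(50, sigma, size=72),
            })
            pooled.append(pooled_intra_sd(plate_estimates(df)))
        assert np.mean(pooled) == pytest.approx(sigma, rel=0.02)


class TestInterPlateSD:
    def test_identical_plate_means_clamp_to_zero(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert inter_plate_sd([5.0, 5.0, 5.0], intra_sd=1.0, k=3) == 0.0

    def test_zero_intra_reduces_to_between_sd(self):
        means = [1.0, 2.0, 4.0]
        assert inter_plate_sd(means, 0.0, 3) == pytest.approx(
            bias_corrected_sd(means)
        )

    def test_direct_formula(self):
        # plate means engineered so the bias-corrected between-SD is known
        means = np.array([0.0, 1.0, 2.0])
        s_between = bias_corrected_sd(means)
        intra, k = 1.5, 3
        expected = math.sqrt(s_between**2 - intra**2 / k)
        assert inter_plate_sd(means, intra, k) == pytest.approx(expected)

    def test_monotone_decreasing_in_claimed_intra(self):
        means = [10.0, 12.0, 15.0]
        sds = [inter_plate_sd(means, s, 3) for s in (0.0, 1.0, 2.0, 3.0)]
        assert all(a >= b for a, b in zip(sds, sds[1:]))

    def test_requires_two_plates(self):
        with pytest.raises(ValueError):
            inter_plate_sd([1.0], 0.5, 3)

    def test_pooled_version_matches_single_group_at_pooled_df(self):
        groups = [np.array([0.0, 1.0, 2.0]), np.array([5.0, 6.0, 8.0])]
        got = pooled_inter_plate_sd(groups, 0.0, 3)
        ss = sum(np.sum((g - g.mean()) ** 2) for g in groups)
        expected = math.sqrt(ss / 4) / c4(5)
        assert got == pytest.approx(expected)


class TestGeometricSD:
    def test_log_identity(self):
        vals = np.exp([0.0, 1.0, 2.0])
        gsd, scale = geometric_sd(vals)
        assert gsd == pytest.approx(bias_corrected_sd([0.0, 1.0, 2.0]))
        assert scale == pytest.approx(math.exp(gsd))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            geometric_sd([1.0, 0.0, 2.0])

    @given(st.floats(0.5, 3.0))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, c):
        vals = np.array([0.9, 1.0, 1.2, 1.5])
        gsd1, _ = geometric_sd(vals)
        gsd2, _ = geometric_sd(c * vals)
        assert gsd1 == pytest.approx(gsd2, abs=1e-12)


class TestResultContainers:
    def test_variance_components_invariants(self):
        vc = VarianceComponents(
            flavor="geometric", sigma_intra=0.0686, sigma_inter=0.0305,
            k=12, sigma_intra_ci=(0.06, 0.08), scale_factor=1.071,
        )
        assert vc.scale_factor >= 1.0
        with pytest.raises(ValueError):
            VarianceComponents(flavor="harmonic", sigma_intra=1, sigma_inter=0, k=3)
        with pytest.raises(ValueError):
            VarianceComponents(flavor="arithmetic", sigma_intra=-1,
                               sigma_inter=0, k=3)
        with pytest.raises(ValueError):
            VarianceComponents(flavor="arithmetic", sigma_intra=1.0,
                               sigma_inter=0, k=3, sigma_intra_ci=(1.5, 2.0))

    def test_regression_result_rejects_invalid_r(self):
        with pytest.raises(ValueError):
            RegressionResult(slope=1, intercept=0, r=1.2, n=5, p_value=0.1)


class TestRegressions:
    def test_perfect_descending_line(self):
        levels = np.array([10, 30, 50, 70, 90], dtype=float)
        sds = 3.4 - 0.034 * levels
        res = fit_sd_vs_level(levels, sds)
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-0.034, abs=1e-10)
        assert res.intercept == pytest.approx(3.4, abs=1e-8)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_sd_vs_level([5, 5, 5], [1, 2, 3])

    def test_slope_recovery_from_noisy_linear_truth(self, rng):
        levels = np.tile([10, 20, 40, 60, 80], 20).astype(float)
        truth_slope = -0.034
        sds = 3.4 + truth_slope * levels + rng.normal(0, 0.05, size=levels.size)
        res = fit_sd_vs_level(levels, sds)
        se = 0.05 / np.sqrt(np.sum((levels - levels.mean()) ** 2))
        assert abs(res.slope - truth_slope) < 3 * se

    def test_spearman_monotone_extremes(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert spearman_sd_vs_cq(x, np.exp(x)).r == pytest.approx(1.0)
        assert spearman_sd_vs_cq(x, -np.exp(x)).r == pytest.approx(-1.0)

    def test_spearman_equals_rank_then_pearson(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = spearman_sd_vs_cq(x, y)
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))
        assert res.r == pytest.approx(oracle.statistic, abs=1e-10)

    def test_spearman_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_sd_vs_cq([1, 1, 1, 1], [1, 2, 3, 4])
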