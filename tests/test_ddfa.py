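"""Scaling-exponent engine: fluctuation functions, the finite-difference
stencil, the sliding DDFA field, smoothness-priors detrending and the
short-term exponent track."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvthresh import (
    ScaleGrid,
    alpha1_track,
    ddfa,
    dfa2_fluctuation,
    gen_fgn,
    local_alpha,
    smoothness_priors_detrend,
)
from hrvthresh.series import RRISeries

GRID = ScaleGrid.log_spaced()


def exact_expected_alpha(scale: int, hurst: float) -> float:
    """Oracle: exact expected stencil exponent at one scale for fGn(H),
    from the profile covariance and the order-2 projection."""
    logF = {}
    for w in (scale - 1, scale, scale + 1):
        i = np.arange(w)
        V = np.vander(i.astype(float), 3, increasing=True)
        H = V @ np.linalg.solve(V.T @ V, V.T)
        k = np.abs(np.subtract.outer(i, i)).astype(float)
        gam = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                     + np.abs(k - 1) ** (2 * hurst))
        A = np.tril(np.ones((w, w)))
        rss = np.trace((np.eye(w) - H) @ (A @ gam @ A.T))
        logF[w] = 0.5 * np.log(rss / w)
    return local_alpha(logF[scale - 1], logF[scale], logF[scale + 1], scale)


class TestScaleGrid:
    def test_default_grid_bounds_and_uniqueness(self):
        s = GRID.scales
        assert s.min() == 5 and s.max() == 64
        assert np.unique(s).size == s.size <= 20

    def test_log_spacings_positive(self):
        assert (GRID.h_minus > 0).all() and (GRID.h_plus > 0).all()

    def test_rejects_scales_below_five(self):
        with pytest.raises(ValueError):
            ScaleGrid(scales=np.array([3, 8]))


class TestFluctuationFunction:
    def test_quadratic_profile_annihilated(self):
        # linear intervals integrate to a quadratic profile, which the
        # order-2 window fit removes exactly
        x = 700.0 + 0.5 * np.arange(200)
        assert dfa2_fluctuation(x, 10) == pytest.approx(0.0, abs=1e-8)

    def test_too_short_segment_masked_not_raised(self):
        assert np.isnan(dfa2_fluctuation(np.ones(8), 10))
        assert np.isnan(dfa2_fluctuation(np.ones(50), 3))

    def test_white_noise_slope_matches_exact_expectation(self):
        # oracle: exact E[F^2] over the grid from the white-noise profile
        # covariance; the sampled log-log slope must agree with the
        # oracle's slope (which is above 1/2 at these scales because the
        # order-2 fit suppresses small-scale fluctuations)
        rng = np.random.default_rng(31)
        x = rng.standard_normal(10_000)
        F = np.array([dfa2_fluctuation(x, int(s)) for s in GRID.scales])
        slope = np.polyfit(np.log(GRID.scales), np.log(F), 1)[0]
        exp_F = []
        for s in GRID.scales:
            i = np.arange(s)
            V = np.vander(i.astype(float), 3, increasing=True)
            H = V @ np.linalg.solve(V.T @ V, V.T)
            Sig = np.minimum.outer(i, i) + 1.0
            exp_F.append(np.sqrt(np.trace((np.eye(s) - H) @ Sig) / s))
        oracle_slope = np.polyfit(np.log(GRID.scales), np.log(exp_F), 1)[0]
        assert slope == pytest.approx(oracle_slope, abs=0.03)
        assert 0.5 < oracle_slope < 0.6

    def test_fgn_slope_recovers_hurst(self):
        x = gen_fgn(10_000, 0.9, seed=5)
        F = np.array([dfa2_fluctuation(x, int(s)) for s in GRID.scales])
        slope = np.polyfit(np.log(GRID.scales), np.log(F), 1)[0]
        assert slope == pytest.approx(0.9, abs=0.1)


class TestLocalAlpha:
    def test_linear_logF_gives_unit_slope(self):
        for s in (5, 10, 37, 64):
            a = local_alpha(np.log(s - 1.0), np.log(float(s)), np.log(s + 1.0), s)
            assert a == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_weighted_difference_form(self):
        # algebraically independent formulation of the non-uniform first
        # derivative: [ (h-/h+)(F+ - F0) + (h+/h-)(F0 - F-) ] / (h- + h+),
        # which collapses to the plain central difference when h- = h+
        rng = np.random.default_rng(2)
        for s in (5, 10, 29, 64):
            fm, f0, fp = rng.normal(size=3)
            hm = np.log(s) - np.log(s - 1)
            hp = np.log(s + 1) - np.log(s)
            oracle = ((hm / hp) * (fp - f0) + (hp / hm) * (f0 - fm)) / (hm + hp)
            assert local_alpha(fm, f0, fp, s) == pytest.approx(oracle, rel=1e-12)

    def test_frozen_value_from_symbolic_oracle(self):
        # F~ = (0, 0.35, 0.68) at s = 10; expected value frozen from an
        # exact rational/log evaluation of the stencil formula
        assert local_alpha(0.0, 0.35, 0.68, 10) == pytest.approx(
            3.39567063505180, abs=1e-11
        )

    def test_nonfinite_input_masked(self):
        assert np.isnan(local_alpha(-np.inf, 0.3, 0.6, 10))
        assert np.isnan(local_alpha(np.nan, 0.3, 0.6, 10))

    @given(
        b=st.floats(-2, 2),
        c=st.floats(-1, 1),
        s=st.integers(min_value=5, max_value=64),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_on_log_quadratic(self, b, c, s):
        # F~(u) = a + b log u + c (log u)^2 has derivative b + 2c log u;
        # a 3-point stencil differentiates any quadratic exactly
        logs = np.log(np.array([s - 1.0, s, s + 1.0]))
        f = 0.7 + b * logs + c * logs**2
        expected = b + 2 * c * np.log(s)
        assert abs(local_alpha(f[0], f[1], f[2], s) - expected) < 1e-10


def brute_force_alpha(x, t, scale, factor=5):
    """Independent oracle: per-segment local profile, per-window polyfit."""
    l = factor * scale
    a = t - l // 2
    seg = x[a : a + l]
    logF = []
    for w in (scale - 1, scale, scale + 1):
        prof = np.cumsum(seg - seg.mean())
        ms = []
        for j in range(l - w + 1):
            y = prof[j : j + w]
            coef = np.polyfit(np.arange(w), y, 2)
            ms.append(np.mean((y - np.polyval(coef, np.arange(w))) ** 2))
        logF.append(np.log(np.sqrt(np.mean(ms))))
    return local_alpha(logF[0], logF[1], logF[2], scale)


class TestDDFAField:
    def test_matches_brute_force_oracle(self):
        x = 700 + 25 * gen_fgn(600, 0.8, seed=2)
        field = ddfa(RRISeries.from_intervals(x), GRID)
        for t, s in [(200, 5), (300, 15), (280, 33), (320, 64)]:
            j = int(np.flatnonzero(GRID.scales == s)[0])
            oracle = brute_force_alpha(x, t, s)
            assert abs(field.alpha[t, j] - oracle) / abs(oracle) < 1e-10

    def test_white_noise_per_scale_matches_exact_expectation(self):
        rng = np.random.default_rng(7)
        x = 700 + 20 * rng.standard_normal(10_000)
        field = ddfa(RRISeries.from_intervals(x), GRID)
        for j, s in enumerate(GRID.scales):
            measured = np.nanmean(field.alpha[:, j])
            assert measured == pytest.approx(
                exact_expected_alpha(int(s), 0.5), abs=0.1
            ), f"scale {s}"

    def test_smoothness_across_interior_scales(self):
        # the small-scale stencil points have few residual degrees of
        # freedom and are biased high; from scale 10 upward the per-scale
        # means of pure fGn are flat
        x = 700 + 20 * gen_fgn(10_000, 0.9, seed=8)
        field = ddfa(RRISeries.from_intervals(x), GRID)
        means = np.nanmean(field.alpha, axis=0)
        interior = means[GRID.scales >= 10]
        assert interior.max() - interior.min() < 0.15

    def test_planted_nonstationarity_detected(self):
        half1 = gen_fgn(3000, 0.95, seed=3)
        half2 = gen_fgn(3000, 0.5, seed=4)
        x = 700 + 20 * np.concatenate([half1, half2])
        field = ddfa(RRISeries.from_intervals(x), GRID)
        j = int(np.flatnonzero(GRID.scales == 9)[0])
        n = x.size
        first = np.nanmean(field.alpha[: n // 4, j])
        last = np.nanmean(field.alpha[3 * n // 4 :, j])
        assert first - last >= 0.3

    def test_segment_hr_is_mean_heart_rate(self):
        x = np.full(400, 600.0)  # 100 BPM
        field = ddfa(RRISeries.from_intervals(x), GRID)
        assert np.nanmin(field.seg_hr) == pytest.approx(100.0)
        assert np.nanmax(field.seg_hr) == pytest.approx(100.0)

    def test_edges_masked_not_zero_filled(self):
        x = 700 + 20 * gen_fgn(400, 0.8, seed=9)
        field = ddfa(RRISeries.from_intervals(x), GRID)
        j = int(np.flatnonzero(GRID.scales == 13)[0])
        l = 5 * 13
        assert np.isnan(field.alpha[: l // 2, j]).all()
        assert np.isfinite(field.alpha[l // 2, j])

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            ddfa(RRISeries.from_intervals(np.full(20, 700.0)), GRID)

    def test_hop_subsamples_time(self):
        x = 700 + 20 * gen_fgn(500, 0.8, seed=10)
        dense = ddfa(RRISeries.from_intervals(x), GRID)
        hopped = ddfa(RRISeries.from_intervals(x), GRID, hop=5)
        j = 0
        defined = np.flatnonzero(np.isfinite(hopped.alpha[:, j]))
        assert np.all(np.diff(defined) == 5)
        np.testing.assert_allclose(
            hopped.alpha[defined, j], dense.alpha[defined, j]
        )


class TestSmoothnessPriors:
    def test_constant_input_fully_detrended(self):
        out = smoothness_priors_detrend(np.full(100, 3.7))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_linear_ramp_absorbed_by_trend(self):
        ramp = np.linspace(0, 100, 500)
        out = smoothness_priors_detrend(ramp, lam=500)
        assert np.max(np.abs(out)) <= 1e-6 * 100

    def test_lambda_zero_returns_zeros(self):
        z = np.random.default_rng(0).normal(size=50)
        np.testing.assert_array_equal(smoothness_priors_detrend(z, lam=0), 0.0)

    def test_matches_dense_solver_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=120)
        lam = 500.0
        m = z.size
        D2 = np.zeros((m - 2, m))
        for i in range(m - 2):
            D2[i, i : i + 3] = (1.0, -2.0, 1.0)
        trend = np.linalg.solve(np.eye(m) + lam**2 * D2.T @ D2, z)
        np.testing.assert_allclose(
            smoothness_priors_detrend(z, lam), z - trend, atol=1e-9
        )

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            smoothness_priors_detrend([1.0, 2.0])


class TestAlpha1Track:
    def test_white_noise_calibrated(self):
        rng = np.random.default_rng(12)
        x = 700 + 20 * rng.standard_normal(6000)
        track = alpha1_track(RRISeries.from_intervals(x))
        assert np.nanmean(track.alpha1) == pytest.approx(0.5, abs=0.1)

    def test_one_over_f_noise_calibrated(self):
        x = 700 + 20 * gen_fgn(6000, 1.0, seed=13)
        track = alpha1_track(RRISeries.from_intervals(x))
        assert np.nanmean(track.alpha1) == pytest.approx(1.0, abs=0.15)

    def test_five_second_spacing(self):
        x = 700 + 20 * gen_fgn(600, 0.8, seed=14)
        track = alpha1_track(RRISeries.from_intervals(x))
        assert np.allclose(np.diff(track.t_grid), 5.0)

    def test_short_recording_raises(self):
        # 119 s of beats cannot host a single 2-minute window
        x = np.full(170, 700.0)  # 119 s
        with pytest.raises(ValueError, match="window"):
            alpha1_track(RRISeries.from_intervals(x))

    def test_track_reports_window_heart_rate(self):
        x = np.full(400, 600.0)
        track = alpha1_track(RRISeries.from_intervals(x))
        assert np.nanmean(track.seg_hr) == pytest.approx(100.0)
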