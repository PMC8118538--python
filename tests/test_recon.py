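"""Unit tests for the PRFS reconstruction pipeline stages."""

import numpy as np
import pytest

import thermowire as tw
from thermowire.recon import FilterConfig, ReconConfig, _trailing_mean


def _series_from_phase(phase, te=0.018, b0=1.5, tr=1.0):
    data = np.exp(1j * phase)
    return tw.ComplexImageSeries(
        data=data,
        times=np.arange(phase.shape[0], dtype=float) * tr,
        pixel_spacing=(0.8, 0.8),
        te=te,
        b0=b0,
        tr=tr,
    )


RAD_PER_DEGC = 2 * np.pi * 42.576e6 * 1.5 * (-9.4e-9) * 0.018  # ≈ −0.0679 rad/°C


class TestBuildReference:
    def test_identical_phases_returned_exactly(self):
        phase = np.full((10, 1, 4, 4), 0.7)
        ref = tw.build_reference(_series_from_phase(phase), 10)
        assert np.allclose(ref, 0.7)

    def test_complex_mean_handles_pi_wrap(self):
        # phases straddling ±π must average to ≈ ±π, not ≈ 0
        phase = np.zeros((2, 1, 1, 1))
        phase[0] = np.pi - 0.01
        phase[1] = -np.pi + 0.01
        ref = tw.build_reference(_series_from_phase(phase), 2)
        expected = np.angle(np.exp(1j * (np.pi - 0.01)) + np.exp(1j * (-np.pi + 0.01)))
        assert abs(ref[0, 0, 0] - expected) < 1e-12
        assert abs(abs(ref[0, 0, 0]) - np.pi) < 1e-9

    def test_reference_noise_reduced_by_sqrt_n(self):
        rng = np.random.default_rng(11)
        sigma = 0.02
        phase = rng.normal(0.0, sigma, (10, 1, 320, 320))
        ref = tw.build_reference(_series_from_phase(phase), 10)
        assert ref.std() == pytest.approx(sigma / np.sqrt(10), rel=0.03)

    def test_too_few_dynamics_rejected(self):
        phase = np.zeros((5, 1, 2, 2))
        with pytest.raises(ValueError, match="fewer"):
            tw.build_reference(_series_from_phase(phase), 10)


class TestPhaseToTemperature:
    def test_zero_phase_gives_zero(self):
        cfg = ReconConfig()
        assert tw.phase_to_temperature(np.zeros(3), cfg, 0.018, 1.5) == pytest.approx(0)

    def test_known_conversion_constant(self):
        # −0.067895 rad at TE 18 ms, 1.5 T is +1 °C
        cfg = ReconConfig()
        dT = tw.phase_to_temperature(np.array([-0.067895]), cfg, 0.018, 1.5)
        assert dT[0] == pytest.approx(1.0, abs=1e-4)

    def test_linearity(self):
        cfg = ReconConfig()
        phi = np.array([0.01, -0.02, 0.5])
        assert np.allclose(
            tw.phase_to_temperature(3 * phi, cfg, 0.018, 1.5),
            3 * tw.phase_to_temperature(phi, cfg, 0.018, 1.5),
        )

    @pytest.mark.parametrize("te,b0", [(0.0, 1.5), (0.018, -1.0)])
    def test_invalid_config_rejected(self, te, b0):
        with pytest.raises(ValueError):
            tw.phase_to_temperature(np.zeros(1), ReconConfig(), te, b0)


class TestDriftCorrection:
    def _noise_series(self, seed=0, n=60, shape=(1, 16, 16)):
        rng = np.random.default_rng(seed)
        return tw.TemperatureSeries(
            dT=rng.normal(0, 0.05, (n, *shape)), times=np.arange(float(n))
        )

    def test_drift_free_series_unchanged(self):
        base = self._noise_series()
        mask = np.ones((1, 16, 16), dtype=bool)
        # a zero-mean stationary series is altered only by its own sampled
        # background mean; a strictly drift-free (all-zero) one is untouched
        zero = tw.TemperatureSeries(dT=np.zeros_like(base.dT), times=base.times)
        out = tw.correct_drift(zero, tw.DriftConfig(background_mask=mask))
        assert np.abs(out.dT).max() < 1e-10

    def test_uniform_linear_drift_removed(self):
        n = 120
        drift = 0.01 * np.arange(n)
        dT = np.broadcast_to(drift[:, None, None, None], (n, 1, 16, 16)).copy()
        series = tw.TemperatureSeries(dT=dT, times=np.arange(float(n)))
        mask = np.ones((1, 16, 16), dtype=bool)
        out = tw.correct_drift(series, tw.DriftConfig(background_mask=mask))
        bg_mean = out.dT.mean(axis=(1, 2, 3))
        # trailing smoothing lags a ramp by (window-1)/2 samples of slope
        assert np.all(np.abs(bg_mean) < 0.05)

    def test_hotspot_preserved_under_drift(self, default_truth, background_mask):
        drift = 0.02 * np.arange(120)
        drifted = tw.TemperatureSeries(
            dT=default_truth.dT + drift[:, None, None, None],
            times=default_truth.times,
        )
        out = tw.correct_drift(drifted, tw.DriftConfig(background_mask=background_mask))
        s, r, c = default_truth.phantom.hotspot_center
        err = np.abs(out.dT[:, s, r, c] - default_truth.dT[:, s, r, c])
        assert err.max() < drift.max()
        # peak change is much smaller than the applied drift amplitude
        assert err[90] < 0.15

    def test_empty_mask_rejected(self):
        series = self._noise_series()
        with pytest.raises(ValueError, match="empty"):
            tw.correct_drift(
                series, tw.DriftConfig(background_mask=np.zeros((1, 16, 16), bool))
            )

    def test_trailing_mean_is_causal(self):
        x = np.zeros(10)
        x[5] = 1.0
        y = _trailing_mean(x[:, None], 3)[:, 0]
        assert np.all(y[:5] == 0)  # no influence before the event


class TestLowpassFilter:
    def test_dc_gain_exactly_one(self):
        series = tw.TemperatureSeries(
            dT=np.full((50, 1, 2, 2), 3.7), times=np.arange(50.0)
        )
        out = tw.lowpass_filter(series)
        assert np.allclose(out.dT, 3.7, atol=1e-12)
        assert out.filtered and out.lag_samples == 3

    def test_white_noise_reduction_matches_bandwidth(self):
        # equivalent-noise-bandwidth prediction: sqrt(fc·π/2 / (fs/2)) ≈ 0.354
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.0, (240, 1, 40, 40))
        series = tw.TemperatureSeries(dT=x, times=np.arange(240.0))
        out = tw.lowpass_filter(series)
        factor = out.dT[20:].std() / x[20:].std()
        assert 0.30 < factor < 0.40

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FilterConfig(cutoff_hz=0.5, sampling_hz=1.0)

    def test_short_series_rejected(self):
        series = tw.TemperatureSeries(
            dT=np.zeros((5, 1, 2, 2)), times=np.arange(5.0)
        )
        with pytest.raises(ValueError, match="warm-up"):
            tw.lowpass_filter(series)


class TestPrecisionMaps:
    def test_constant_series_has_zero_sigma(self):
        series = tw.TemperatureSeries(
            dT=np.full((20, 1, 3, 3), 1.5), times=np.arange(20.0)
        )
        pm = tw.precision_maps(series)
        assert np.allclose(pm.sigma, 0) and np.allclose(pm.mu, 1.5)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.65, (120, 1, 8, 8))
        series = tw.TemperatureSeries(dT=x, times=np.arange(120.0))
        pm = tw.precision_maps(series)
        # brute-force two-pass standard deviation
        mu = x.sum(axis=0) / 120
        sig = np.sqrt(((x - mu) ** 2).sum(axis=0) / 119)
        assert np.allclose(pm.sigma, sig) and np.allclose(pm.mu, mu)
        assert pm.sigma.mean() == pytest.approx(0.65, rel=0.05)
        assert np.abs(pm.mu).max() < 4 * 0.65 / np.sqrt(120)

    def test_single_dynamic_rejected(self):
        series = tw.TemperatureSeries(dT=np.zeros((1, 1, 2, 2)), times=[0.0])
        with pytest.raises(ValueError):
            tw.precision_maps(series)


class TestRoiBoxStats:
    def test_linear_interpolation_quartiles(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        stats = tw.roi_box_stats(vals, np.ones((10, 10), bool))
        assert stats.median == pytest.approx(50.5)
        assert stats.q1 == pytest.approx(25.75)
        assert stats.q3 == pytest.approx(75.25)
        assert stats.lower == 1.0

    def test_constant_map_collapses(self):
        stats = tw.roi_box_stats(np.full((4, 4), 2.0), np.ones((4, 4), bool))
        assert stats.lower == stats.q1 == stats.median == stats.q3 == stats.p95 == 2.0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(3)
        vals = np.abs(rng.normal(0, 0.2, (30, 30)))
        roi = rng.random((30, 30)) > 0.4
        stats = tw.roi_box_stats(vals, roi)
        v = np.sort(vals[roi])
        for got, q in zip(stats, [0, 0.25, 0.5, 0.75, 0.95]):
            assert got == pytest.approx(np.quantile(v, q))

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            tw.roi_box_stats(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestRmseWithLag:
    def test_identical_curves_zero(self):
        x = np.sin(np.linspace(0, 3, 50))
        assert tw.rmse_with_lag(x, x, 0) == 0

    def test_lag_exactly_compensates_delay(self):
        x = np.sin(np.linspace(0, 3, 50))
        delayed = np.concatenate([np.full(3, x[0]), x[:-3]])
        assert tw.rmse_with_lag(delayed, x, 3) == pytest.approx(0, abs=1e-12)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError):
            tw.rmse_with_lag(np.zeros(5), np.zeros(5), 5)


class TestHottestPixel:
    def test_finds_hotspot_center(self, default_truth):
        series = tw.TemperatureSeries(dT=default_truth.dT, times=default_truth.times)
        hp = tw.hottest_pixel(series, (86, 90))
        assert hp.index == default_truth.phantom.hotspot_center

    def test_end_mean_matches_closed_form(self):
        # noiseless trajectory: mean over t ∈ {86..90} of the heating branch
        params = tw.EqOneParams(alpha=0.1, tau=5.0, p0=10.0)
        w = tw.HeatingWindow(10.0, 90.0)
        t = np.arange(120.0)
        curve = tw.eq1_eval(t, params.alpha, params.p0, params.tau, w)
        dT = curve[:, None, None, None] * np.ones((1, 1, 3, 3))
        hp = tw.hottest_pixel(
            tw.TemperatureSeries(dT=dT, times=t), (86, 90)
        )
        expected = np.mean([5 * np.log((tt - 10 + 5) / 5) for tt in range(86, 91)])
        assert hp.mean == pytest.approx(expected, rel=1e-12)

    def test_all_zero_series_first_pixel_tiebreak(self):
        series = tw.TemperatureSeries(
            dT=np.zeros((10, 2, 3, 3)), times=np.arange(10.0)
        )
        hp = tw.hottest_pixel(series, (5, 9))
        assert hp.index == (0, 0, 0) and hp.mean == 0

    def test_window_outside_series_rejected(self):
        series = tw.TemperatureSeries(dT=np.zeros((10, 1, 2, 2)), times=np.arange(10.0))
        with pytest.raises(ValueError):
            tw.hottest_pixel(series, (86, 90))


class TestFwhm:
    def test_gaussian_profile_analytic_width(self):
        s_mm = 1.5
        spacing = 0.1  # fine sampling: interpolation error negligible
        x = (np.arange(201) - 100) * spacing
        profile = np.exp(-(x**2) / (2 * s_mm**2))
        img = np.tile(profile, (3, 1))
        width = tw.fwhm_profile(img, (1, 100), spacing)
        assert width == pytest.approx(2.3548 * s_mm, rel=0.01)

    def test_single_hot_pixel_bounded(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        width = tw.fwhm_profile(img, (2, 2), 0.8)
        assert width <= 1.6

    def test_hotspot_widths_span_observed_range(self):
        # spatial sigmas chosen to give FWHM between 2.4 and 5.6 mm
        for sigma in (1.02, 1.5, 2.37):
            phantom = tw.PhantomSpec(hotspot_sigma=sigma)
            params = tw.EqOneParams(alpha=0.02, tau=10.0, p0=30.0)
            truth = tw.simulate_temperature_field(
                phantom, params, tw.HeatingWindow(10, 90), np.arange(95.0)
            )
            s, r, c = phantom.hotspot_center
            width = tw.fwhm_profile(truth.dT[90, s], (r, c), 0.8)
            assert 2.3 <= width <= 5.7

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            tw.fwhm_profile(np.zeros((5, 5)), (2, 2), 0.8)


class TestReconstructor:
    def test_noiseless_round_trip(self, default_truth, noiseless_series):
        dT = tw.TemperatureReconstructor().fit_transform(noiseless_series)
        assert np.abs(dT.dT - default_truth.dT).max() < 1e-9

    def test_sklearn_param_interface(self):
        est = tw.TemperatureReconstructor(cutoff_hz=0.05)
        assert est.get_params()["cutoff_hz"] == 0.05
        est.set_params(n_reference=5)
        assert est.n_reference == 5

    def test_full_pipeline_recovers_truth_within_noise(
        self, default_truth, background_mask
    ):
        series = tw.simulate_complex_series(
            default_truth,
            noise=tw.NoiseDriftSpec(drift_rate=0.002, seed=21),
        )
        est = tw.TemperatureReconstructor(
            drift_correction=True, background_mask=background_mask
        )
        dT = est.fit_transform(series)
        err = dT.dT - default_truth.dT
        # within 3x the noise-predicted per-sample temperature error
        sigma_pred = 0.0441 * np.sqrt(1 + 1 / 10) / 0.06789
        s, r, c = default_truth.phantom.hotspot_center
        assert np.abs(err[:, s, r, c]).max() < 3.5 * sigma_pred
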