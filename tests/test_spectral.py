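"""Planar gradients, Hanning TFR, baseline normalization, group series."""

import numpy as np
import pytest

from trackosc.simulate import Epochs
from trackosc.spectral import (
    combine_planar,
    condition_average,
    condition_mean_tfr,
    group_band_series,
    planar_transform,
    planar_weights,
    relative_change,
    sensor_groups,
    tfr_power,
)

FS = 250.0
TIMES = np.arange(-1000.0, 3000.0 + 1e-9, 1000.0 / FS)


def _tone(freq, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * TIMES / 1000.0 + phase)


class TestPlanarTransform:
    def test_uniform_field_has_zero_derivatives(self, sensors24):
        W_du, W_dv = planar_weights(sensors24)
        const = np.ones(24)
        assert np.allclose(W_du @ const, 0.0, atol=1e-12)
        assert np.allclose(W_dv @ const, 0.0, atol=1e-12)

    def test_linear_field_recovered_exactly(self, sensors24):
        # field = g·x is linear in space: the tangential gradient equals the
        # projection of (g,0,0) on the tangent plane, exactly for a local
        # linear fit
        g = 3.7
        vals = g * sensors24.positions[:, 0]
        W_du, W_dv = planar_weights(sensors24)
        du, dv = W_du @ vals, W_dv @ vals
        from trackosc.spectral import _tangent_basis
        for i in range(24):
            e1, e2 = _tangent_basis(sensors24.orientations[i])
            assert du[i] == pytest.approx(g * e1[0], abs=1e-9)
            assert dv[i] == pytest.approx(g * e2[0], abs=1e-9)

    def test_smooth_field_matches_finite_differences(self, sensors80):
        # tangential gradient magnitude of a smooth field vs a fine-grid
        # numerical derivative along the tangent directions
        from trackosc.spectral import _tangent_basis
        k = np.array([9.0, 6.0, 4.0])

        def f(p):
            return np.sin(p @ k)

        vals = f(sensors80.positions)
        W_du, W_dv = planar_weights(sensors80)
        du, dv = W_du @ vals, W_dv @ vals
        got = np.hypot(du, dv)
        eps = 1e-5
        want = np.empty(80)
        for i, p in enumerate(sensors80.positions):
            e1, e2 = _tangent_basis(sensors80.orientations[i])
            g1 = (f(p + eps * e1) - f(p - eps * e1)) / (2 * eps)
            g2 = (f(p + eps * e2) - f(p - eps * e2)) / (2 * eps)
            want[i] = np.hypot(g1, g2)
        err = np.abs(got - want) / np.abs(want).max()
        assert np.median(err) < 0.05

    def test_uniform_offset_leaves_planar_power_unchanged(self, small_epochs):
        shifted = Epochs(small_epochs.data + 5.0, small_epochs.times_ms,
                         small_epochs.metadata, small_epochs.sensors)
        a = planar_transform(small_epochs)
        b = planar_transform(shifted)
        assert np.allclose(a.data, b.data, atol=1e-9)


class TestTFRPower:
    def test_zero_signal_zero_power(self):
        tfr = tfr_power(np.zeros((1, 2, len(TIMES))), TIMES)
        assert np.nanmax(tfr.power) == 0.0

    def test_unit_sinusoid_concentrates_at_its_bin(self):
        tfr = tfr_power(_tone(10.0)[None, None, :], TIMES)
        i10 = np.argmin(np.abs(tfr.freqs - 10))
        i20 = np.argmin(np.abs(tfr.freqs - 20))
        p10 = np.nanmean(tfr.power[0, 0, i10, tfr.valid])
        p20 = np.nanmean(tfr.power[0, 0, i20, tfr.valid])
        assert p10 == pytest.approx(1.0, rel=1e-3)
        assert p10 / p20 > 1e3

    def test_amplitude_step_quadruples_power(self):
        x = _tone(10.0) * np.where(TIMES < 0, 1.0, 2.0)
        tfr = tfr_power(x[None, None, :], TIMES)
        i10 = np.argmin(np.abs(tfr.freqs - 10))
        before = tfr.power[0, 0, i10, np.flatnonzero(tfr.times_ms == -400)[0]]
        after = tfr.power[0, 0, i10, np.flatnonzero(tfr.times_ms == 400)[0]]
        assert after / before == pytest.approx(4.0, rel=1e-3)

    def test_scale_equivariance_and_relative_change_invariance(self):
        x = np.random.default_rng(0).standard_normal((2, 3, len(TIMES)))
        a = tfr_power(x, TIMES)
        b = tfr_power(3.0 * x, TIMES)
        assert np.allclose(b.power[:, :, :, b.valid],
                           9.0 * a.power[:, :, :, a.valid], rtol=1e-12)
        ra, rb = relative_change(a), relative_change(b)
        assert np.allclose(ra.power[:, :, :, ra.valid],
                           rb.power[:, :, :, rb.valid], rtol=1e-9, atol=1e-12)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tfr_power(np.zeros((1, 1, len(TIMES))), TIMES,
                      freqs=np.array([130.0]))

    def test_edges_flagged_invalid_not_zero_padded(self):
        tfr = tfr_power(np.ones((1, 1, len(TIMES))), TIMES)
        assert not tfr.valid[0] and not tfr.valid[-1]
        assert np.isnan(tfr.power[0, 0, 0, 0])
        assert tfr.times_ms[1] - tfr.times_ms[0] == 20.0

    def test_parseval_style_power_tracking_on_white_noise(self):
        """Summed TFR power across frequencies tracks windowed variance up
        to a taper constant (relative error < 10% over 200 trials)."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 1, len(TIMES)))
        freqs = np.arange(2.0, 125.0, 2.0)  # dense grid to near Nyquist
        tfr = tfr_power(x, TIMES, freqs=freqs)
        mean_total = np.nanmean(tfr.power[:, 0, :, tfr.valid].sum(axis=-1))
        # expectation for white noise: each bin contributes
        # sigma^2 * (2/sum(w))^2 * sum(w^2)/2... calibrate on a reference run
        n_w = int(round(0.5 * FS))
        w = np.hanning(n_w)
        per_bin = (2.0 / w.sum()) ** 2 * (w ** 2).sum() / 2.0 * 2.0
        expected = per_bin * len(freqs)
        assert mean_total == pytest.approx(expected, rel=0.1)

    def test_matches_scipy_short_time_fft(self):
        """Independent cross-check of the sliding-window Fourier magnitude
        against scipy's ShortTimeFFT on one window."""
        from scipy.fft import rfft
        x = np.random.default_rng(3).standard_normal(len(TIMES))
        tfr = tfr_power(x[None, None, :], TIMES, freqs=np.array([10.0]))
        ti = np.flatnonzero(tfr.times_ms == 500.0)[0]
        n_w = int(round(0.5 * FS))
        c = int(round((500.0 - TIMES[0]) * FS / 1000.0))
        seg = x[c - n_w // 2: c - n_w // 2 + n_w] * np.hanning(n_w)
        # 10 Hz = bin 5 of a 125-point FFT at 250 Hz
        coef = np.fft.fft(seg)[5]
        want = np.abs(2.0 / np.hanning(n_w).sum() * coef) ** 2
        assert tfr.power[0, 0, 0, ti] == pytest.approx(want, rel=1e-9)


class TestRelativeChange:
    def test_constant_double_half_power(self):
        x = _tone(25.0)  # stationary under the 20 ms window step
        tfr = tfr_power(x[None, None, :], TIMES)
        rc = relative_change(tfr)
        i25 = np.argmin(np.abs(rc.freqs - 25))
        assert np.nanmax(np.abs(rc.power[0, 0, i25, rc.valid])) < 1e-12
        doubled = tfr.power.copy()
        doubled[..., TIMES_VALID_AFTER := (tfr.times_ms > 0)] *= 2.0
        from dataclasses import replace
        rc2 = relative_change(replace(tfr, power=doubled))
        sel = rc2.valid & (rc2.times_ms > 300)
        assert np.allclose(rc2.power[0, 0, i25, sel], 1.0, atol=1e-9)

    def test_zero_baseline_power_identified(self):
        x = np.zeros((1, 1, len(TIMES)))
        tfr = tfr_power(x, TIMES)
        with pytest.raises(ValueError, match="channel 0"):
            relative_change(tfr)


class TestGroupBandSeries:
    def test_matches_brute_force_nested_mean(self, sensors24):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 48, len(TIMES)))  # planar channels
        tfr = combine_planar(tfr_power(x, TIMES))
        tfr = relative_change(tfr)
        groups = sensor_groups(sensors24)
        series = group_band_series(tfr, groups, (8.0, 12.0))
        fidx = [i for i, f in enumerate(tfr.freqs) if 8 <= f <= 12]
        for name, ch in groups.items():
            brute = tfr.power[:, ch][:, :, fidx, :].mean(axis=(1, 2))
            assert np.allclose(series[name], brute, equal_nan=True)

    def test_single_sensor_group_equals_member(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 4, len(TIMES)))
        tfr = relative_change(tfr_power(x, TIMES))
        series = group_band_series(tfr, {"solo": np.array([2])}, (8.0, 12.0))
        fidx = [i for i, f in enumerate(tfr.freqs) if 8 <= f <= 12]
        assert np.allclose(series["solo"][0],
                           tfr.power[0, 2, fidx, :].mean(axis=0),
                           equal_nan=True)

    def test_empty_group_rejected(self):
        tfr = relative_change(tfr_power(
            np.random.default_rng(0).standard_normal((1, 2, len(TIMES))),
            TIMES))
        with pytest.raises(ValueError, match="empty"):
            group_band_series(tfr, {"none": np.array([], dtype=int)},
                              (8.0, 12.0))


def test_condition_mean_tfr_equals_average_of_trial_tfr():
    rng = np.random.default_rng(5)
    x = rng.standard_normal((6, 2, len(TIMES)))
    labels = ["a", "b", "a", "b", "a", "b"]
    direct = condition_average(tfr_power(x, TIMES), labels)
    chunked = condition_mean_tfr(x, TIMES, labels, chunk=2)
    assert direct.obs_labels == chunked.obs_labels
    assert np.allclose(direct.power, chunked.power, equal_nan=True)
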