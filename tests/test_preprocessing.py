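"""Cleaning, filtering, normalization and segmentation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actipred.io import RawRecording, SignalEpoch
from actipred.preprocessing import (
    PreprocessConfig,
    clean_record,
    lowpass_filter,
    normalize_global,
    segment_epochs,
    smooth_moving_average,
    split_epoch,
)


def _rec(channels, fs=100.0, activity=4):
    n = channels.shape[0]
    return RawRecording(
        timestamps=np.arange(n) / fs,
        activity_ids=np.full(n, activity),
        channels=channels,
        sampling_rate=fs,
    )


class TestCleanRecord:
    def test_edge_trim_sample_count(self, rng):
        rec = _rec(rng.normal(0, 1, (8000, 6)))
        out = clean_record(rec, PreprocessConfig(edge_trim_s=35.0))
        assert out.n_samples == 1000

    def test_too_short_record_errors(self, rng):
        rec = _rec(rng.normal(0, 1, (7000, 6)))
        with pytest.raises(ValueError, match="too short"):
            clean_record(rec, PreprocessConfig(edge_trim_s=35.0))

    def test_missing_sample_in_zero_channel_becomes_zero(self):
        x = np.zeros((500, 6))
        x[100, 2] = np.nan
        out = clean_record(_rec(x), PreprocessConfig(edge_trim_s=0.5))
        assert out.channels[100 - 50, 2] == 0.0
        assert np.all(np.isfinite(out.channels))

    def test_outlier_replaced_by_mean_of_unflagged(self, rng):
        x = rng.normal(0, 1, (2000, 1))
        x[700, 0] = 100.0
        cfg = PreprocessConfig(edge_trim_s=1.0, outlier_zscore=4.0)
        out = clean_record(_rec(x), cfg)
        kept = x[100:-100, 0]
        # independent z-score oracle on the trimmed segment
        z = (kept - kept.mean()) / kept.std()
        flagged = np.abs(z) > 4.0
        assert flagged[600]
        expect = kept[~flagged].mean()
        assert out.channels[600, 0] == pytest.approx(expect)
        assert np.abs(out.channels[:, 0]).max() < 100.0


class TestLowpass:
    def test_dc_passes_unchanged(self):
        x = np.full((1000, 2), 3.7)
        y = lowpass_filter(x, 15.0, 100.0)
        np.testing.assert_allclose(y, x, atol=1e-6)

    @pytest.mark.parametrize(
        "freq,min_amp,max_amp", [(5.0, 0.95, 1.05), (30.0, 0.0, 0.10)]
    )
    def test_passband_and_stopband_amplitude(self, freq, min_amp, max_amp):
        fs, n = 100.0, 2000  # both test tones fall on exact FFT bins
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, 15.0, fs)
        # spectral-peak amplitude oracle
        amp = 2 * np.abs(np.fft.rfft(y)) / n
        k = int(round(freq * n / fs))
        assert min_amp <= amp[k] <= max_amp

    def test_nyquist_violation_errors(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_filter(np.zeros((100, 1)), 15.0, 25.0)

    def test_short_signal_errors(self):
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_filter(np.zeros((10, 1)), 15.0, 100.0)


class TestNormalizeGlobal:
    def test_zero_mean_channel_scales_to_unit(self):
        y = normalize_global(np.array([[-2.0], [0.0], [2.0]]))
        np.testing.assert_allclose(y[:, 0], [-1, 0, 1])

    def test_global_divisor_shared_across_channels(self):
        x = np.array([[-2.0, -1.0], [0.0, 0.0], [2.0, 1.0]])
        y = normalize_global(x)
        np.testing.assert_allclose(y[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(y[:, 1], [-0.5, 0, 0.5])

    def test_constant_channel_maps_to_zero(self):
        x = np.array([[5.0, -1.0], [5.0, 0.0], [5.0, 1.0]])
        y = normalize_global(x)
        np.testing.assert_allclose(y[:, 0], 0.0)

    def test_all_constant_input_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            y = normalize_global(np.full((4, 2), 3.0))
        np.testing.assert_array_equal(y, 0.0)

    def test_output_bounded_and_idempotent(self, rng):
        x = rng.normal(0, 5, (300, 6))
        y = normalize_global(x)
        assert np.max(np.abs(y)) <= 1.0 + 1e-12
        np.testing.assert_allclose(normalize_global(y), y, atol=1e-12)

    def test_per_channel_mode_unit_max_every_channel(self, rng):
        y = normalize_global(rng.normal(0, 5, (300, 3)), per_channel=True)
        np.testing.assert_allclose(np.max(np.abs(y), axis=0), 1.0)


class TestMovingAverage:
    def test_constant_signal_unchanged(self):
        x = np.full((50, 2), 2.5)
        np.testing.assert_allclose(smooth_moving_average(x, 5), x)

    def test_impulse_spreads_to_fifth(self):
        x = np.zeros((101, 1))
        x[50] = 1.0
        y = smooth_moving_average(x, 5)[:, 0]
        np.testing.assert_allclose(y[48:53], 0.2)
        np.testing.assert_allclose(y[:48], 0.0)

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(40.0)[:, None]
        y = smooth_moving_average(x, 5)[:, 0]
        np.testing.assert_allclose(y[2:-2], x[2:-2, 0], atol=1e-12)

    def test_even_or_oversized_window_errors(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_moving_average(np.zeros((10, 1)), 4)
        with pytest.raises(ValueError, match="larger"):
            smooth_moving_average(np.zeros((3, 1)), 5)


class TestSegmentation:
    @pytest.mark.parametrize("length,stride,expect", [
        (1024, 512, 2), (1024, 256, 3), (511, 256, 0), (512, 256, 1),
    ])
    def test_window_counts(self, length, stride, expect, rng):
        cfg = PreprocessConfig(window_stride=stride)
        seg = _rec(np.clip(rng.normal(0, 0.3, (length, 6)), -1, 1))
        epochs = segment_epochs(seg, cfg, label="walk")
        assert len(epochs) == expect
        for e in epochs:
            assert e.data.shape == (512, 6)
            assert e.label == "walk"

    @settings(max_examples=40, deadline=None)
    @given(
        length=st.integers(512, 4000),
        stride=st.integers(1, 600),
    )
    def test_count_closed_form(self, length, stride):
        cfg = PreprocessConfig(window_stride=stride)
        seg = _rec(np.zeros((length, 6)))
        n = len(segment_epochs(seg, cfg, label="walk"))
        assert n == (length - 512) // stride + 1

    def test_windows_tile_the_signal(self, rng):
        x = np.clip(rng.normal(0, 0.3, (1024, 6)), -1, 1)
        cfg = PreprocessConfig(window_stride=512)
        epochs = segment_epochs(_rec(x), cfg, label="run")
        np.testing.assert_array_equal(epochs[0].data, x[:512])
        np.testing.assert_array_equal(epochs[1].data, x[512:])


class TestSplitEpoch:
    def test_halves_and_reconstruction(self):
        ramp = np.linspace(-1, 1, 512)
        data = np.tile(ramp[:, None], (1, 6))
        ep = SignalEpoch(data=data, label="walk")
        pair = split_epoch(ep)
        assert pair.observed.shape == (256, 6)
        assert pair.future.shape == (256, 6)
        assert pair.observed[-1, 0] == ramp[255]
        assert pair.future[0, 0] == ramp[256]
        np.testing.assert_array_equal(pair.reconstruct(), data)

    def test_odd_length_errors(self):
        ep = SignalEpoch(data=np.zeros((511, 6)), label="walk")
        with pytest.raises(ValueError, match="even"):
            split_epoch(ep)
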