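"""Forecaster construction, training and autoregressive inference."""

import numpy as np
import pytest

from actipred.forecasters import (
    ARCHITECTURES,
    ForecasterSpec,
    TrainConfig,
    build_forecaster,
    fit_forecaster,
    forecast,
)
from actipred.io import EpochPair
from actipred.metrics import corr, rmse


def tiny_spec(arch, **kw):
    base = dict(
        conv2lstm_units=8, conv2lstm_proj=8, seq2seq_units=8,
        d_mod=8, pe_ma_units=8, n_heads=2, dropout=0.1,
    )
    base.update(kw)
    return ForecasterSpec(architecture=arch, **base)


def sine_pairs(n_pairs, rng, noise=0.0):
    pairs = []
    for _ in range(n_pairs):
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(512) / 100.0
        x = 0.8 * np.sin(2 * np.pi * 2.0 * t + phase)[:, None]
        data = np.tile(x, (1, 6)) + rng.normal(0, noise, (512, 6))
        data = np.clip(data, -1, 1)
        pairs.append(EpochPair(observed=data[:256], future=data[256:],
                               label="walk"))
    return pairs


class TestBuild:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_same_seed_identical_parameters(self, arch):
        a = build_forecaster(tiny_spec(arch), seed=7)
        b = build_forecaster(tiny_spec(arch), seed=7)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_forecast_shape_and_finiteness_untrained(self, arch, rng):
        model = build_forecaster(tiny_spec(arch), seed=0)
        out = forecast(model, np.zeros((256, 6)))
        assert out.shape == (256, 6)
        assert np.all(np.isfinite(out))

    def test_unknown_architecture_errors(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            ForecasterSpec(architecture="transformer")

    def test_heads_must_divide_width(self):
        with pytest.raises(ValueError, match="divisible"):
            ForecasterSpec(pe_ma_units=30, n_heads=16)


class TestFit:
    def test_empty_dataset_errors(self):
        model = build_forecaster(tiny_spec("conv2lstm"), seed=0)
        with pytest.raises(ValueError, match="empty"):
            fit_forecaster(model, [], TrainConfig(n_passes=1))

    def test_zero_future_target_learned(self, rng):
        # future identically zero is the simplest learnable map
        pairs = [
            EpochPair(observed=np.clip(rng.normal(0, 0.3, (256, 6)), -1, 1),
                      future=np.zeros((256, 6)), label="walk")
            for _ in range(8)
        ]
        model = build_forecaster(tiny_spec("conv2lstm"), seed=0)
        fit_forecaster(model, pairs, TrainConfig(n_passes=40, batch_size=8,
                                                 lr=3e-3, seed=0))
        pred = forecast(model, pairs[0].observed)
        assert rmse(pairs[0].future, pred) < 0.05

    def test_single_sinusoid_overfit_to_high_corr(self, rng):
        pairs = sine_pairs(1, rng) * 4
        model = build_forecaster(tiny_spec("seq2seq_lstm", seq2seq_units=16),
                                 seed=0)
        hist = fit_forecaster(
            model, pairs,
            TrainConfig(n_passes=240, batch_size=4, lr=3e-3, seed=0,
                        tf_noise_sd=0.0),
        )
        assert hist[-1] < hist[0]
        pred = forecast(model, pairs[0].observed)
        assert corr(pairs[0].future, pred) >= 0.99

    def test_same_seed_identical_histories(self, rng):
        pairs = sine_pairs(4, rng, noise=0.02)
        cfg = TrainConfig(n_passes=3, batch_size=2, seed=5)
        h1 = fit_forecaster(build_forecaster(tiny_spec("seq2seq_lstm_pe_ma"),
                                             seed=1), pairs, cfg)
        h2 = fit_forecaster(build_forecaster(tiny_spec("seq2seq_lstm_pe_ma"),
                                             seed=1), pairs, cfg)
        assert h1 == h2

    def test_loss_trends_downward(self, rng):
        pairs = sine_pairs(6, rng, noise=0.02)
        model = build_forecaster(tiny_spec("seq2seq_lstm"), seed=2)
        hist = fit_forecaster(model, pairs,
                              TrainConfig(n_passes=30, batch_size=6, lr=3e-3,
                                          seed=0))
        assert hist[-1] < hist[0]


class TestForecastContract:
    def test_wrong_input_shape_errors(self):
        model = build_forecaster(tiny_spec("seq2seq_lstm"), seed=0)
        with pytest.raises(ValueError, match="expected input shape"):
            forecast(model, np.zeros((100, 6)))

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_inference_deterministic_and_pure(self, arch, rng):
        model = build_forecaster(tiny_spec(arch), seed=3)
        x = np.clip(rng.normal(0, 0.3, (256, 6)), -1, 1)
        before = [p.value.copy() for p in model.parameters()]
        a = forecast(model, x)
        b = forecast(model, x)
        np.testing.assert_array_equal(a, b)
        for p, orig in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.value, orig)

    def test_batched_matches_single(self, rng):
        model = build_forecaster(tiny_spec("seq2seq_lstm_pe_ma"), seed=0)
        X = np.clip(rng.normal(0, 0.3, (3, 256, 6)), -1, 1)
        batch = forecast(model, X)
        for i in range(3):
            np.testing.assert_allclose(batch[i], forecast(model, X[i]),
                                       atol=1e-10)


class TestCheckpointRoundTrip:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_save_load_preserves_predictions(self, arch, tmp_path, rng):
        from actipred.serialize import load_model, save_model

        model = build_forecaster(tiny_spec(arch), seed=4)
        x = np.clip(rng.normal(0, 0.3, (256, 6)), -1, 1)
        want = forecast(model, x)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(forecast(back, x), want)
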