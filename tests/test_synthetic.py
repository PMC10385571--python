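"""Generator closed forms, reproducibility, artifacts and separability."""

import numpy as np
import pytest

from actipred.io import load_pamap2
from actipred.synthetic import (
    DEFAULT_ACTIVITY_MODELS,
    ActivityModel,
    SyntheticDatasetConfig,
    generate_hap_dataset,
    generate_recording,
    spectral_peak_label,
    write_pamap2,
)


def pure_tone_model(f0=2.0, **kw):
    base = dict(
        fundamental_hz=f0,
        harmonics=((1.0, 1.0),),
        channel_gains=(1.0,) * 6,
        channel_phases=(0.0,) * 6,
        noise_sd=0.0,
        freq_jitter=0.0,
        amp_jitter=0.0,
        nan_rate=0.0,
        outlier_rate=0.0,
    )
    base.update(kw)
    return ActivityModel(**base)


class TestGenerateRecording:
    def test_noiseless_single_harmonic_closed_form(self):
        rec = generate_recording(
            {"walk": pure_tone_model()}, [("walk", 10.0)], seed=0,
            phase_jitter=False,
        )
        expect = np.sin(2 * np.pi * 2.0 * rec.timestamps)
        for c in range(6):
            np.testing.assert_allclose(rec.channels[:, c], expect, atol=1e-12)

    def test_same_seed_reproducible(self):
        kw = dict(
            models=DEFAULT_ACTIVITY_MODELS,
            schedule=[("walk", 5.0), ("run", 5.0)],
            seed=42,
        )
        a = generate_recording(**kw)
        b = generate_recording(**kw)
        np.testing.assert_array_equal(a.channels, b.channels)
        np.testing.assert_array_equal(a.activity_ids, b.activity_ids)

    def test_schedule_sets_activity_ids(self):
        rec = generate_recording(
            DEFAULT_ACTIVITY_MODELS, [("walk", 2.0), ("run", 3.0)], seed=0
        )
        assert (rec.activity_ids[:200] == 4).all()
        assert (rec.activity_ids[200:] == 5).all()
        assert rec.n_samples == 500

    def test_nan_injection_count_binomial(self):
        p = 0.01
        n = 100_000
        model = pure_tone_model(nan_rate=p)
        rec = generate_recording({"walk": model}, [("walk", n / 100.0)], seed=3)
        count = int(np.isnan(rec.channels).sum())
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(count - n * p) <= 3 * sigma

    def test_empty_schedule_errors(self):
        with pytest.raises(ValueError, match="empty"):
            generate_recording(DEFAULT_ACTIVITY_MODELS, [], seed=0)


class TestPamap2RoundTrip:
    def test_written_file_loads_through_real_reader(self, tmp_path):
        rec = generate_recording(
            DEFAULT_ACTIVITY_MODELS, [("walk", 3.0), ("run", 2.0)], seed=5
        )
        path = tmp_path / "syn.dat"
        write_pamap2(rec, path)
        back = load_pamap2(path)
        assert back.n_samples == rec.n_samples
        np.testing.assert_array_equal(back.activity_ids, rec.activity_ids)
        np.testing.assert_allclose(back.channels, rec.channels, rtol=1e-4,
                                   atol=1e-4)


class TestHapDataset:
    def test_counts_and_epoch_invariants(self):
        cfg = SyntheticDatasetConfig(epochs_per_class=12)
        ds = generate_hap_dataset(cfg, seed=0)
        total = len(ds.train) + len(ds.test)
        assert abs(total - 5 * 12) <= 5 * 2  # one boundary epoch dropped/class
        for pair in ds.train + ds.test:
            assert pair.observed.shape == (256, 6)
            assert pair.future.shape == (256, 6)
            assert np.all(np.isfinite(pair.observed))
            assert np.max(np.abs(pair.future)) <= 1.0 + 1e-9
        # balanced within a couple of windows
        labels = [p.label for p in ds.train]
        counts = [labels.count(name) for name in ds.label_names]
        assert max(counts) - min(counts) <= 2

    def test_train_test_disjoint_in_time(self):
        ds = generate_hap_dataset(SyntheticDatasetConfig(epochs_per_class=10), seed=1)
        # no test observation window may reproduce a training future window
        for tr in ds.train[:5]:
            for te in ds.test[:5]:
                assert not np.array_equal(tr.future, te.observed)

    def test_spectral_peak_recovers_fundamental(self):
        cfg = SyntheticDatasetConfig(epochs_per_class=8, noise_sd=0.01)
        ds = generate_hap_dataset(cfg, seed=2)
        funds = {k: v.fundamental_hz for k, v in DEFAULT_ACTIVITY_MODELS.items()}
        fs = 100.0
        for ep in ds.test_epochs:
            x = ep.data[:, 0] - ep.data[:, 0].mean()
            spec = np.abs(np.fft.rfft(x))
            freqs = np.fft.rfftfreq(len(x), d=1 / fs)
            peak = freqs[np.argmax(spec[1:]) + 1]
            # within one FFT bin (plus jitter slack) of the true fundamental
            assert abs(peak - funds[ep.label]) <= fs / len(x) + 0.15

    def test_spectral_classifier_near_perfect(self):
        cfg = SyntheticDatasetConfig(epochs_per_class=20, noise_sd=0.02)
        ds = generate_hap_dataset(cfg, seed=3)
        funds = {k: v.fundamental_hz for k, v in DEFAULT_ACTIVITY_MODELS.items()}
        hits = [
            spectral_peak_label(ep.data, 100.0, funds) == ep.label
            for ep in ds.train_epochs + ds.test_epochs
        ]
        assert np.mean(hits) >= 0.99

    def test_future_continues_observed_without_seam(self):
        # quasi-periodicity: the jump across the split point is no larger
        # than typical one-step increments within each half
        ds = generate_hap_dataset(SyntheticDatasetConfig(epochs_per_class=6), seed=4)
        for pair in ds.test:
            step = np.abs(np.diff(pair.reconstruct(), axis=0))
            seam = step[255]
            typical = step.mean(axis=0) + 5 * step.std(axis=0)
            assert np.all(seam <= typical)
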