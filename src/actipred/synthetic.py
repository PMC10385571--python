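"""Synthetic quasi-periodic activity-signal generator.

Emulates 100 Hz, 6-channel accelerometer recordings of cyclic daily
activities: each activity is a harmonic series at a characteristic gait
frequency, with per-channel gains and phases, additive Gaussian noise, and
injected NaN / outlier artifacts mimicking wireless dropouts.  Default
fundamentals follow the cadence ordering walk < Nordic walk < stairs ascend
< stairs descend < run; they are configuration values, not measurements of
any real dataset.

The generator is the test bed for the whole pipeline: signals are learnable
(distinct fundamentals make a trivial spectral-peak classifier near-perfect)
and quasi-periodic (the future half of an epoch continues the observed half
seamlessly), so forecasting is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import EpochPair, RawRecording, SignalEpoch, PAMAP2_N_COLUMNS, CHANNEL_SETS
from .preprocessing import PreprocessConfig, preprocess_recording, split_epoch


@dataclass
class ActivityModel:
    """Spectral recipe for one activity's 6-channel signal.

    ``freq_jitter`` and ``amp_jitter`` add slow stride-to-stride variability
    (relative SD of the instantaneous rate and envelope, modelled as
    Ornstein-Uhlenbeck processes with ~2 s correlation time), making the
    signal quasi-periodic rather than strictly periodic, as real gait is.
    """

    fundamental_hz: float
    harmonics: tuple[tuple[float, float], ...] = ((1.0, 1.0), (2.0, 0.45), (3.0, 0.2))
    channel_gains: tuple[float, ...] = (1.0, 0.8, 0.6, 0.9, 0.7, 0.5)
    channel_phases: tuple[float, ...] = (0.0, 0.7, 1.4, 2.1, 2.8, 3.5)
    noise_sd: float = 0.05
    freq_jitter: float = 0.02
    amp_jitter: float = 0.08
    jitter_tau_s: float = 2.0
    nan_rate: float = 0.001
    outlier_rate: float = 0.0005

    def __post_init__(self) -> None:
        if not 0 < self.fundamental_hz < 15:
            raise ValueError("fundamental must lie inside the 15 Hz passband")


def _ou_process(rng: np.random.Generator, n: int, dt: float, tau: float,
                sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples (mean 0, SD ``sd``)."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    s = sd * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, s, size=n - 1) if n > 1 else np.empty(0)
    for k in range(1, n):
        x[k] = a * x[k - 1] + eps[k - 1]
    return x


#: Synthetic stand-ins for the five configured activities; PAMAP2 codes are
#: reused so the same label mapping drives real and synthetic data.
DEFAULT_ACTIVITY_MODELS: dict[str, ActivityModel] = {
    "walk": ActivityModel(fundamental_hz=1.4),
    "nordic_walk": ActivityModel(fundamental_hz=1.9),
    "stairs_ascend": ActivityModel(fundamental_hz=2.4),
    "stairs_descend": ActivityModel(fundamental_hz=2.9),
    "run": ActivityModel(fundamental_hz=3.4),
}

SYNTHETIC_ACTIVITY_CODES: dict[str, int] = {
    "walk": 4,
    "run": 5,
    "nordic_walk": 7,
    "stairs_ascend": 12,
    "stairs_descend": 13,
}


def generate_recording(
    models: dict[str, ActivityModel],
    schedule: list[tuple[str, float]],
    fs: float = 100.0,
    seed: int = 0,
    subject_id: str = "syn01",
    activity_codes: dict[str, int] | None = None,
    phase_jitter: bool = True,
) -> RawRecording:
    """Synthesize a recording following a (activity, duration_s) schedule.

    During a scheduled block of activity ``a``, channel ``c`` is
    ``gain_c * sum_h amp_h * sin(2*pi*mult_h*f0*t + phase_c + jitter)`` plus
    Gaussian noise; each block draws a random phase offset per channel (when
    ``phase_jitter``) so models cannot memorize absolute time.  Artifacts:
    with probability ``nan_rate`` a sample gets a NaN in one random channel,
    with ``outlier_rate`` a large spike.  Fully reproducible by ``seed``.
    """
    if not schedule:
        raise ValueError("schedule is empty")
    codes = activity_codes if activity_codes is not None else SYNTHETIC_ACTIVITY_CODES
    rng = np.random.default_rng(seed)
    chunks, id_chunks = [], []
    t_offset = 0.0
    for name, dur in schedule:
        if dur <= 0:
            raise ValueError(f"non-positive duration for {name!r}")
        model = models[name]
        n = int(round(dur * fs))
        t = t_offset + np.arange(n) / fs
        gains = np.asarray(model.channel_gains)
        phases = np.asarray(model.channel_phases, dtype=float).copy()
        if phase_jitter:
            phases += rng.uniform(0, 2 * np.pi, size=phases.shape)
        dt = 1.0 / fs
        # instantaneous phase integrates a jittered rate; envelope wanders
        rate = model.fundamental_hz * (
            1.0 + _ou_process(rng, n, dt, model.jitter_tau_s, model.freq_jitter)
        )
        cum = np.concatenate(([0.0], np.cumsum(rate[:-1]))) * dt
        phi = 2 * np.pi * (model.fundamental_hz * t_offset + cum)
        env = 1.0 + _ou_process(rng, n, dt, model.jitter_tau_s, model.amp_jitter)
        x = np.zeros((n, gains.size))
        for mult, amp in model.harmonics:
            x += amp * np.sin(mult * phi[:, None] + phases[None, :])
        x *= env[:, None] * gains[None, :]
        if model.noise_sd > 0:
            x += rng.normal(0.0, model.noise_sd, size=x.shape)
        # artifact injection: one affected channel per flagged sample
        if model.nan_rate > 0:
            hit = rng.random(n) < model.nan_rate
            ch = rng.integers(0, x.shape[1], size=n)
            x[hit, ch[hit]] = np.nan
        if model.outlier_rate > 0:
            hit = rng.random(n) < model.outlier_rate
            ch = rng.integers(0, x.shape[1], size=n)
            spike = rng.choice([-1.0, 1.0], size=n) * rng.uniform(20, 50, size=n)
            x[hit, ch[hit]] = spike[hit]
        chunks.append(x)
        id_chunks.append(np.full(n, codes[name], dtype=int))
        t_offset = t[-1] + 1.0 / fs
    channels = np.concatenate(chunks)
    ids = np.concatenate(id_chunks)
    n_total = channels.shape[0]
    return RawRecording(
        timestamps=np.arange(n_total) / fs,
        activity_ids=ids,
        channels=channels,
        subject_id=subject_id,
        sampling_rate=fs,
    )


def write_pamap2(rec: RawRecording, path) -> None:
    """Write a recording as PAMAP2-format 54-column text.

    The six channels are placed at the chest/ankle ±16 g accelerometer
    columns; all other sensor columns are NaN, as in real dropout-affected
    files.  This lets the real reader be exercised on synthetic data.
    """
    cols = CHANNEL_SETS["chest_ankle_acc16g"]
    table = np.full((rec.n_samples, PAMAP2_N_COLUMNS), np.nan)
    table[:, 0] = rec.timestamps
    table[:, 1] = rec.activity_ids
    table[:, 2] = 0.0  # heart rate placeholder
    table[:, 3:21] = 0.0
    table[:, 21:] = 0.0
    for i, c in enumerate(cols):
        table[:, c] = rec.channels[:, i]
    np.savetxt(path, table, fmt="%.6g")


@dataclass
class SyntheticDatasetConfig:
    """Study conditions for the synthetic train/test corpus.

    ``epochs_per_class`` counts 512-sample epochs produced per activity at
    50 % window overlap; ``train_frac`` splits them by contiguous time blocks
    (one boundary epoch is dropped so train and test share no samples).
    """

    epochs_per_class: int = 50
    activities: tuple[str, ...] = tuple(DEFAULT_ACTIVITY_MODELS)
    noise_sd: float | None = None
    train_frac: float = 0.8
    fs: float = 100.0
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(edge_trim_s=2.0)
    )
    models: dict[str, ActivityModel] | None = None


@dataclass
class HapDataset:
    train: list[EpochPair]
    test: list[EpochPair]
    label_names: list[str]
    train_epochs: list[SignalEpoch]
    test_epochs: list[SignalEpoch]

    def arrays(self, split: str = "train"):
        pairs = self.train if split == "train" else self.test
        X = np.stack([p.observed for p in pairs])
        Y = np.stack([p.future for p in pairs])
        labels = np.array([self.label_names.index(p.label) for p in pairs])
        return X, Y, labels


def generate_hap_dataset(config: SyntheticDatasetConfig | None = None,
                         seed: int = 0) -> HapDataset:
    """Generate, preprocess and split a labeled epoch-pair corpus.

    One contiguous block per activity is synthesized, run through the full
    preprocessing stack (clean, low-pass, normalize, smooth, segment), split
    into epoch pairs, and divided into disjoint train/test spans per class.
    """
    config = config or SyntheticDatasetConfig()
    if len(config.activities) < 2:
        raise ValueError("need at least two activities")
    models = dict(config.models or DEFAULT_ACTIVITY_MODELS)
    if config.noise_sd is not None:
        models = {k: replace(v, noise_sd=config.noise_sd) for k, v in models.items()}
    cfg = config.preprocess
    W = cfg.epoch_samples(config.fs)
    S = cfg.window_stride
    n = config.epochs_per_class
    # samples needed for n windows, plus trim margins and a smoothing pad
    need = W + (n - 1) * S + int(2 * cfg.edge_trim_s * config.fs) + S
    dur = need / config.fs
    label_names = sorted(config.activities)
    train_ep: list[SignalEpoch] = []
    test_ep: list[SignalEpoch] = []
    for i, name in enumerate(label_names):
        rec = generate_recording(
            models, [(name, dur)], fs=config.fs, seed=seed * 1009 + i,
            subject_id=f"syn{seed:03d}",
        )
        epochs = preprocess_recording(
            rec, cfg, activities=[name], activity_codes=SYNTHETIC_ACTIVITY_CODES
        )
        k = int(round(config.train_frac * len(epochs)))
        train_ep.extend(epochs[:k])
        # drop one boundary epoch: overlapping windows straddle the split
        test_ep.extend(epochs[k + 1:])
    return HapDataset(
        train=[split_epoch(e) for e in train_ep],
        test=[split_epoch(e) for e in test_ep],
        label_names=label_names,
        train_epochs=train_ep,
        test_epochs=test_ep,
    )


def spectral_peak_label(signal: np.ndarray, fs: float,
                        fundamentals: dict[str, float]) -> str:
    """Classify a (samples x channels) signal by its dominant frequency.

    Finds the FFT peak of the channel-summed power spectrum and returns the
    activity whose fundamental lies nearest.  Serves as the independent
    separability oracle for the deep classifier.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = x - x.mean(axis=0, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
    power = spec.sum(axis=1)
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / fs)
    peak = freqs[np.argmax(power[1:]) + 1]
    names = list(fundamentals)
    dists = [abs(peak - fundamentals[n]) for n in names]
    return names[int(np.argmin(dists))]
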