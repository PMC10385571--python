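"""Cleaning, filtering, normalization and sliding-window segmentation.

The fixed stage order is: edge-trim / artifact replacement -> zero-phase
low-pass -> mean removal + global normalization -> moving-average smoothing ->
activity selection -> overlapping-window segmentation into 5.12 s epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig

from .io import (
    DEFAULT_ACTIVITY_CODES,
    EpochPair,
    RawRecording,
    SignalEpoch,
    activity_name,
    filter_by_activity,
)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    edge_trim_s
        Seconds discarded from both ends of every recording (sensor strap-on /
        strap-off transients); default 35 s.
    lowpass_cutoff_hz
        Cutoff of the zero-phase low-pass applied per channel; default 15 Hz
        (human movement energy lies below ~15 Hz at 100 Hz sampling).
    ma_window
        Width in samples of the centered moving-average smoother; default 5.
    epoch_s
        Epoch length in seconds; default 5.12 s = 512 samples at 100 Hz, so
        the observed/future halves split evenly at 256.
    window_stride
        Sliding-window step in samples; default 256 (50 % overlap).
    outlier_zscore
        Per-channel |z| threshold above which a sample is treated as an
        artifact and replaced by the channel mean; default 4.0.
    """

    edge_trim_s: float = 35.0
    lowpass_cutoff_hz: float = 15.0
    ma_window: int = 5
    epoch_s: float = 5.12
    window_stride: int = 256
    outlier_zscore: float = 4.0
    per_channel_norm: bool = False
    filter_order: int = 4

    def epoch_samples(self, fs: float) -> int:
        n = self.epoch_s * fs
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9 or n_int % 2:
            raise ValueError("epoch_s x sampling_rate must be an even integer")
        return n_int


def clean_record(rec: RawRecording, cfg: PreprocessConfig) -> RawRecording:
    """Trim record edges and replace missing/outlier samples by channel means.

    The first and last ``edge_trim_s`` seconds are dropped.  Within the
    retained span, each NaN sample and each sample whose per-channel z-score
    exceeds ``outlier_zscore`` is replaced by that channel's mean computed
    over the unflagged samples.  The output contains no missing values.
    """
    n_trim = int(round(cfg.edge_trim_s * rec.sampling_rate))
    if rec.n_samples <= 2 * n_trim:
        raise ValueError(
            f"record too short after edge trim: {rec.n_samples} samples "
            f"<= 2 x {n_trim}"
        )
    out = rec.slice(n_trim, rec.n_samples - n_trim)
    x = out.channels.copy()
    for c in range(x.shape[1]):
        col = x[:, c]
        finite = np.isfinite(col)
        if not finite.any():
            col[:] = 0.0
            continue
        mu = col[finite].mean()
        sd = col[finite].std()
        bad = ~finite
        if sd > 0:
            z = np.zeros_like(col)
            z[finite] = (col[finite] - mu) / sd
            bad = bad | (np.abs(z) > cfg.outlier_zscore)
        good = ~bad
        col[bad] = col[good].mean() if good.any() else mu
    return replace(out, channels=x)


def lowpass_filter(
    x: np.ndarray, cutoff_hz: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass, applied independently per channel.

    Forward-backward filtering (``filtfilt``) doubles the effective order and
    cancels phase lag, so filtered epochs stay time-aligned with their
    forecast targets.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {fs} Hz must exceed 2 x cutoff {cutoff_hz} Hz")
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    b, a = _sig.butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[0] <= padlen:
        raise ValueError(
            f"signal length {x.shape[0]} too short for filter warm-up ({padlen})"
        )
    y = _sig.filtfilt(b, a, x, axis=0)
    return y[:, 0] if squeeze else y


def normalize_global(x: np.ndarray, per_channel: bool = False) -> np.ndarray:
    """Remove per-channel means, then scale into [-1, 1].

    By default a single divisor — the global maximum absolute value across
    all channels after mean removal — is shared by every channel, preserving
    relative channel amplitudes.  ``per_channel=True`` scales each channel by
    its own max-abs instead.  An all-constant channel maps to zeros.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    y = x - x.mean(axis=0, keepdims=True)
    if per_channel:
        scale = np.max(np.abs(y), axis=0, keepdims=True)
        scale = np.where(scale == 0, 1.0, scale)
        y = y / scale
    else:
        scale = np.max(np.abs(y))
        if scale == 0:
            warnings.warn("normalize_global: input is constant; returning zeros")
            return y[:, 0] if squeeze else y
        y = y / scale
    return y[:, 0] if squeeze else y


def smooth_moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving mean per channel; edges use shrinking windows.

    Output length equals input length: at position t the mean is taken over
    the intersection of [t-w//2, t+w//2] with the signal support.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if window > n:
        raise ValueError(f"window {window} larger than signal length {n}")
    kernel = np.ones(window)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    y = np.empty_like(x)
    for c in range(x.shape[1]):
        y[:, c] = np.convolve(x[:, c], kernel, mode="same") / counts
    return y[:, 0] if squeeze else y


def segment_epochs(
    segment: RawRecording,
    cfg: PreprocessConfig,
    label: str | None = None,
    activity_codes: dict[str, int] | None = None,
) -> list[SignalEpoch]:
    """Slide a window of ``epoch_s`` seconds over a single-activity segment.

    Windows start every ``window_stride`` samples (0-based, half-open); a
    trailing remainder shorter than one window is discarded, giving
    floor((L - W) / S) + 1 epochs for L >= W and none otherwise.
    """
    W = cfg.epoch_samples(segment.sampling_rate)
    S = int(cfg.window_stride)
    if S < 1:
        raise ValueError("window_stride must be >= 1")
    if label is None:
        ids = np.unique(segment.activity_ids)
        if ids.size != 1:
            raise ValueError("segment must contain a single activity")
        label = activity_name(int(ids[0]), activity_codes)
    L = segment.n_samples
    epochs: list[SignalEpoch] = []
    for start in range(0, L - W + 1, S):
        epochs.append(
            SignalEpoch(
                data=segment.channels[start : start + W].copy(),
                label=label,
                subject_id=segment.subject_id,
            )
        )
    return epochs


def split_epoch(epoch: SignalEpoch) -> EpochPair:
    """Split an epoch into its observed (first) and future (second) halves."""
    n = epoch.data.shape[0]
    if n % 2:
        raise ValueError("epoch length must be even")
    h = n // 2
    return EpochPair(
        observed=epoch.data[:h].copy(),
        future=epoch.data[h:].copy(),
        label=epoch.label,
        subject_id=epoch.subject_id,
    )


def preprocess_recording(
    rec: RawRecording,
    cfg: PreprocessConfig | None = None,
    activities=None,
    activity_codes: dict[str, int] | None = None,
) -> list[SignalEpoch]:
    """Run the full preprocessing stack on one raw recording.

    clean -> low-pass -> normalize -> smooth -> select activities -> segment.
    Normalization statistics are computed over the whole retained recording
    (all of its activity segments jointly).
    """
    cfg = cfg or PreprocessConfig()
    codes = activity_codes if activity_codes is not None else DEFAULT_ACTIVITY_CODES
    if activities is None:
        activities = list(codes)
    cleaned = clean_record(rec, cfg)
    x = lowpass_filter(
        cleaned.channels, cfg.lowpass_cutoff_hz, cleaned.sampling_rate, cfg.filter_order
    )
    x = normalize_global(x, per_channel=cfg.per_channel_norm)
    x = smooth_moving_average(x, cfg.ma_window)
    prepped = replace(cleaned, channels=x)
    epochs: list[SignalEpoch] = []
    for seg in filter_by_activity(prepped, activities, codes):
        epochs.extend(segment_epochs(seg, cfg, activity_codes=codes))
    return epochs
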