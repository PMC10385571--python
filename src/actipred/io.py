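"""Reading PAMAP2-format recordings and persisting epoch datasets.

PAMAP2 ``.dat`` files are whitespace-separated text with 54 columns per row:
timestamp (s), activity ID, heart rate (bpm), then three 17-column IMU blocks
for the hand, chest and ankle sensors.  Each IMU block is laid out as
temperature, 3x acc (±16 g), 3x acc (±6 g), 3x gyro, 3x magnetometer and a
4-column orientation quaternion.  This package consumes only the ±16 g
tri-axial accelerometers of the chest and ankle IMUs (six channels).

Missing values (wireless dropouts) appear as ``NaN`` tokens or blank cells in
the raw files; both are mapped to the ``numpy.nan`` sentinel on load.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, replace

import h5py
import numpy as np

#: 0-based column indices of the chest and ankle ±16 g accelerometers in the
#: documented 54-column PAMAP2 layout (1-based columns 22-24 and 39-41).
PAMAP2_N_COLUMNS = 54
CHANNEL_SETS: dict[str, tuple[int, ...]] = {
    "chest_ankle_acc16g": (21, 22, 23, 38, 39, 40),
}
#: Canonical channel order used throughout the package.
CHANNEL_NAMES: tuple[str, ...] = (
    "chest_acc_x",
    "chest_acc_y",
    "chest_acc_z",
    "ankle_acc_x",
    "ankle_acc_y",
    "ankle_acc_z",
)

#: Default activity-label -> PAMAP2 integer code mapping.  Kept as data (not
#: hard-coded into any algorithm) so synthetic recordings may use other codes.
DEFAULT_ACTIVITY_CODES: dict[str, int] = {
    "walk": 4,
    "run": 5,
    "nordic_walk": 7,
    "stairs_ascend": 12,
    "stairs_descend": 13,
}


class Pamap2ParseError(ValueError):
    """Raised when a raw recording file cannot be parsed."""


@dataclass
class RawRecording:
    """A timestamped multichannel sample stream with per-sample activity IDs.

    ``channels`` is a float array of shape (n_samples, n_channels) in m/s²;
    missing samples are ``nan`` until :func:`actipred.preprocessing.clean_record`
    runs.
    """

    timestamps: np.ndarray
    activity_ids: np.ndarray
    channels: np.ndarray
    subject_id: str = "unknown"
    sampling_rate: float = 100.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.activity_ids = np.asarray(self.activity_ids, dtype=int)
        self.channels = np.asarray(self.channels, dtype=float)
        n = self.timestamps.shape[0]
        if self.activity_ids.shape[0] != n or self.channels.shape[0] != n:
            raise ValueError("timestamps, activity_ids and channels must align")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def slice(self, start: int, stop: int) -> "RawRecording":
        """Return the half-open sample range [start, stop) as a new recording."""
        return replace(
            self,
            timestamps=self.timestamps[start:stop],
            activity_ids=self.activity_ids[start:stop],
            channels=self.channels[start:stop],
        )


@dataclass
class SignalEpoch:
    """One fixed-length preprocessed window (512 samples x 6 channels).

    Values are normalized accelerations in [-1, 1]; ``label`` is the activity
    name and ``subject_id`` identifies the source recording.
    """

    data: np.ndarray
    label: str
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (samples x channels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if np.max(np.abs(self.data)) > 1.0 + 1e-9:
            raise ValueError("epoch data must lie in [-1, 1]")


@dataclass
class EpochPair:
    """An epoch split into its observed first half and future second half."""

    observed: np.ndarray
    future: np.ndarray
    label: str
    subject_id: str = "unknown"

    def reconstruct(self) -> np.ndarray:
        return np.concatenate([self.observed, self.future], axis=0)


def load_pamap2(
    path,
    channel_selection: str | tuple[int, ...] = "chest_ankle_acc16g",
    subject_id: str | None = None,
) -> RawRecording:
    """Read a PAMAP2-format whitespace-separated text file.

    Parameters
    ----------
    path:
        Path to a ``.dat`` file with the documented 54-column layout.
    channel_selection:
        Name of a set in :data:`CHANNEL_SETS`, or an explicit tuple of
        0-based column indices.  Default: chest + ankle ±16 g accelerometers,
        always in chest-x/y/z, ankle-x/y/z order.

    Returns
    -------
    RawRecording
        With exactly the requested channels; missing-value tokens (``NaN`` or
        blank) become ``numpy.nan``.  No rows are dropped.
    """
    if isinstance(channel_selection, str):
        try:
            cols = CHANNEL_SETS[channel_selection]
        except KeyError:
            raise KeyError(
                f"unknown channel set {channel_selection!r}; "
                f"available: {sorted(CHANNEL_SETS)}"
            ) from None
    else:
        cols = tuple(channel_selection)

    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise Pamap2ParseError(f"{path}: file is empty")

    try:
        table = np.loadtxt(_stdio.StringIO("\n".join(lines)), ndmin=2)
        if table.shape[1] != PAMAP2_N_COLUMNS:
            raise ValueError("wrong column count")
    except ValueError:
        # Slow path purely to produce a line-numbered diagnostic.
        for i, ln in enumerate(lines, start=1):
            fields = ln.split()
            if len(fields) != PAMAP2_N_COLUMNS:
                raise Pamap2ParseError(
                    f"{path}: row {i} has {len(fields)} columns, "
                    f"expected {PAMAP2_N_COLUMNS}"
                ) from None
            for tok in fields:
                try:
                    float(tok)
                except ValueError:
                    raise Pamap2ParseError(
                        f"{path}: row {i}: unparseable value {tok!r}"
                    ) from None
        raise  # pragma: no cover - loadtxt failed for another reason

    names = tuple(
        CHANNEL_NAMES[i] if cols == CHANNEL_SETS["chest_ankle_acc16g"] else f"col{c}"
        for i, c in enumerate(cols)
    )
    return RawRecording(
        timestamps=table[:, 0],
        activity_ids=table[:, 1].astype(int),
        channels=table[:, list(cols)],
        subject_id=subject_id or "unknown",
        channel_names=names,
    )


def filter_by_activity(
    rec: RawRecording,
    activities,
    activity_codes: dict[str, int] | None = None,
) -> list[RawRecording]:
    """Keep contiguous runs of samples whose activity is in ``activities``.

    Each maximal run is returned as its own single-activity
    :class:`RawRecording` segment, in temporal order.  ``activities`` may hold
    label names (resolved through ``activity_codes``, default PAMAP2 mapping)
    or raw integer IDs.
    """
    codes = activity_codes if activity_codes is not None else DEFAULT_ACTIVITY_CODES
    wanted: set[int] = set()
    for a in activities:
        if isinstance(a, str):
            if a not in codes:
                raise KeyError(
                    f"unknown activity label {a!r}; valid labels: {sorted(codes)}"
                )
            wanted.add(codes[a])
        else:
            wanted.add(int(a))

    ids = rec.activity_ids
    segments: list[RawRecording] = []
    n = ids.shape[0]
    start = 0
    while start < n:
        if ids[start] not in wanted:
            start += 1
            continue
        stop = start + 1
        while stop < n and ids[stop] == ids[start]:
            stop += 1
        segments.append(rec.slice(start, stop))
        start = stop
    return segments


def activity_name(code: int, activity_codes: dict[str, int] | None = None) -> str:
    codes = activity_codes if activity_codes is not None else DEFAULT_ACTIVITY_CODES
    for name, c in codes.items():
        if c == code:
            return name
    raise KeyError(f"no label configured for activity ID {code}")


def save_epochs(epochs: list[SignalEpoch], path) -> None:
    """Persist epochs to a single HDF5 container (bit-exact round trip)."""
    labels = sorted({e.label for e in epochs})
    label_index = {name: i for i, name in enumerate(labels)}
    n = len(epochs)
    if n:
        data = np.stack([e.data for e in epochs])
    else:
        data = np.zeros((0, 0, 0))
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset(
            "labels", data=np.array([label_index[e.label] for e in epochs], dtype=int)
        )
        f.create_dataset("label_names", data=np.array(labels, dtype=h5py.string_dtype()))
        f.create_dataset(
            "subject_ids",
            data=np.array([e.subject_id for e in epochs], dtype=h5py.string_dtype()),
        )


def load_epochs(path) -> list[SignalEpoch]:
    """Reload a container written by :func:`save_epochs`."""
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        labels = f["labels"][...]
        label_names = [s.decode() for s in f["label_names"][...]]
        subject_ids = [s.decode() for s in f["subject_ids"][...]]
    return [
        SignalEpoch(data=data[i], label=label_names[labels[i]], subject_id=subject_ids[i])
        for i in range(len(labels))
    ]
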