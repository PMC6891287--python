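"""Reading and writing grasp-and-lift EEG CSV pairs and epoch extraction.

The on-disk dialect is two parallel CSV files: a *data* file with an ``id``
column plus one column per electrode (signal in µV, one row per sample at
500 Hz), and an *events* file with the same ``id`` column plus one binary
column per grasp-and-lift event.  Six events are tracked, in fixed order:
handstart (HS), grasp (GS), lift (LT), hold (HD), replace (RP) and
release (RL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Fixed event order used everywhere in the package.
EVENT_NAMES: tuple[str, ...] = ("HS", "GS", "LT", "HD", "RP", "RL")

#: The six channels over motor (C3, Cz, C4) and parietal (P3, Pz, P4) cortex.
MOTOR_PARIETAL_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4", "P3", "Pz", "P4")

#: Non-event label used for sliding windows during which no event is active.
REST_LABEL: int = -1


class AlignmentError(ValueError):
    """Data and events files disagree on row count or ids."""


class FormatError(ValueError):
    """A CSV file does not follow the expected column layout."""


class ChannelLookupError(KeyError):
    """Requested channels are absent from the recording."""


@dataclass
class EEGRecording:
    """Multichannel EEG signal: ``data`` is (n_channels, n_samples) in µV."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    series_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.n_samples < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EventAnnotations:
    """Per-sample binary activity of the six events; ``labels`` is (6, n_samples)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(EVENT_NAMES):
            raise ValueError("labels must be a (6, n_samples) matrix")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("event annotations must be binary")
        self.labels = self.labels.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.labels.shape[1]


@dataclass
class EpochSet:
    """Fixed-length labelled windows: ``epochs`` is (n_epochs, n_channels, n_window).

    ``labels[i]`` is the event index (0-5, order of :data:`EVENT_NAMES`) active on
    a strict majority of window samples, or :data:`REST_LABEL` for rest windows.
    """

    epochs: np.ndarray
    labels: np.ndarray
    window_length: int
    step: int
    channel_names: list[str] = field(default_factory=list)
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_window)")
        if self.epochs.shape[2] != self.window_length:
            raise ValueError("epoch length disagrees with window_length")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def epochs_for(self, label: int) -> np.ndarray:
        """All epochs carrying ``label`` as a (k, n_channels, n_window) array."""
        return self.epochs[self.labels == label]


def read_recording(data_path, events_path) -> tuple[EEGRecording, EventAnnotations]:
    """Load a data/events CSV pair into an aligned recording and annotation set.

    Both files must have an ``id`` column; ids are opaque strings checked only
    for row-wise equality between the two files.  Gzip-compressed files are
    handled transparently by the CSV reader.
    """
    data = pd.read_csv(data_path)
    events = pd.read_csv(events_path)
    if "id" not in data.columns or "id" not in events.columns:
        raise FormatError("both CSV files must have an 'id' column")
    if len(data) != len(events):
        raise AlignmentError(
            f"row count mismatch: {len(data)} data rows vs {len(events)} event rows"
        )
    if not (data["id"].astype(str).values == events["id"].astype(str).values).all():
        raise AlignmentError("id columns of data and events files disagree")
    ev_cols = [c for c in events.columns if c != "id"]
    if set(ev_cols) != set(EVENT_NAMES):
        unknown = sorted(set(ev_cols) - set(EVENT_NAMES))
        missing = sorted(set(EVENT_NAMES) - set(ev_cols))
        raise FormatError(f"unexpected event columns {unknown}, missing {missing}")
    channels = [c for c in data.columns if c != "id"]
    rec = EEGRecording(
        data=data[channels].to_numpy(dtype=float).T,
        fs=500.0,
        channel_names=channels,
    )
    ann = EventAnnotations(labels=events[list(EVENT_NAMES)].to_numpy().T)
    return rec, ann


def write_recording(
    rec: EEGRecording,
    ann: EventAnnotations,
    data_path,
    events_path,
    float_format: str | None = None,
) -> None:
    """Write a recording and its annotations as a data/events CSV pair.

    With the default ``float_format=None`` the full float repr is written so a
    subsequent :func:`read_recording` reproduces every sample bit-exactly; pass
    e.g. ``"%.6f"`` for fixed 6-decimal output.
    """
    if rec.n_samples != ann.n_samples:
        raise AlignmentError("recording and annotations disagree on sample count")
    ids = [f"s{i}" for i in range(rec.n_samples)]
    df = pd.DataFrame({"id": ids})
    for name, row in zip(rec.channel_names, rec.data):
        df[name] = row
    df.to_csv(data_path, index=False, float_format=float_format)
    ev = pd.DataFrame({"id": ids})
    for name, row in zip(EVENT_NAMES, ann.labels):
        ev[name] = row
    ev.to_csv(events_path, index=False)


def select_channels(rec: EEGRecording, names: list[str]) -> EEGRecording:
    """Return a recording restricted to ``names``, rows reordered to that order."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise ChannelLookupError(f"channels not in recording: {missing}")
    idx = [rec.channel_names.index(n) for n in names]
    return replace(rec, data=rec.data[idx].copy(), channel_names=list(names))


def window_starts(n_samples: int, window_length: int, step: int) -> np.ndarray:
    """Start samples of a sliding window: 0, step, 2·step, … while the window fits."""
    if window_length > n_samples:
        raise ValueError(
            f"window of {window_length} samples exceeds signal of {n_samples}"
        )
    if not 0 < step <= window_length:
        raise ValueError("step must satisfy 0 < step <= window_length")
    n_win = (n_samples - window_length) // step + 1
    return np.arange(n_win) * step


def _window_label(labels: np.ndarray) -> int:
    """Majority label of one window; ties go to the earlier event in fixed order."""
    counts = labels.sum(axis=1)
    k = int(np.argmax(counts))  # argmax is first-max -> HS>GS>... tie-break
    if counts[k] * 2 > labels.shape[1]:  # strict majority of window samples
        return k
    return REST_LABEL


def extract_epochs(
    rec: EEGRecording,
    ann: EventAnnotations,
    window_length: int = 400,
    step: int = 300,
) -> EpochSet:
    """Cut a recording into sliding windows and label each by majority event.

    Defaults follow the 400-sample window with 100-sample overlap used for
    scalogram generation.  Windows are half-open ``[start, start+window_length)``;
    a window is assigned event *k* only if event *k* is active on a strict
    majority of its samples, otherwise it is labelled rest.
    """
    if rec.n_samples != ann.n_samples:
        raise AlignmentError("recording and annotations disagree on sample count")
    starts = window_starts(rec.n_samples, window_length, step)
    epochs = np.stack([rec.data[:, s : s + window_length] for s in starts])
    labels = np.array(
        [_window_label(ann.labels[:, s : s + window_length]) for s in starts],
        dtype=int,
    )
    return EpochSet(
        epochs=epochs,
        labels=labels,
        window_length=window_length,
        step=step,
        channel_names=list(rec.channel_names),
        starts=starts,
    )
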