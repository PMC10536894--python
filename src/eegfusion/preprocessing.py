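"""Signal conditioning for motor-imagery EEG: epoching, windowing, filtering.

The pipeline turns a continuous annotated recording into fixed-shape labeled
arrays: notch/band-pass filtering on the continuous signal, epoch extraction
around event annotations, partition of each epoch into non-overlapping
windows that inherit the epoch's class label, and z-scoring with statistics
from the training partition only.

Conventions: 0-based sample indexing; event intervals are half-open
``[onset, onset + duration)``; trailing partial epochs/windows are dropped
(and counted in the log), never padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Subjects of the 109-subject PhysioNet motor movement/imagery corpus whose
#: runs carry inconsistent annotations; they are dropped from analyses.
EEGMMIDB_EXCLUDED_SUBJECTS = frozenset({38, 82, 88, 89, 100, 104})


@dataclass
class AnnotatedRecording:
    """Continuous multi-channel signal plus labeled event intervals.

    signal is (n_channels, n_samples) in microvolts. Events are
    (onset_sample, duration_samples, label) with 0-based, half-open
    intervals, sorted by onset and non-overlapping.
    """

    signal: np.ndarray
    sampling_rate_hz: float
    channel_names: list[str]
    events: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (n_channels, n_samples)")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.signal.shape[0]} signal rows"
            )
        n = self.signal.shape[1]
        prev_end = 0
        for onset, dur, label in self.events:
            if onset < 0 or dur < 0 or onset + dur > n:
                raise ValueError(
                    f"event ({onset}, {dur}, {label!r}) outside [0, {n})"
                )
            if onset < prev_end:
                raise ValueError("events must be sorted and non-overlapping")
            prev_end = onset + dur

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochSet:
    """Fixed-length trial segments: (n_epochs, C, W_epoch) plus labels."""

    epochs: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, C, W)")
        if self.labels.shape != (self.epochs.shape[0],):
            raise ValueError("labels must have one entry per epoch")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("labels must index into class_names")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]


@dataclass
class WindowedDataset:
    """Network-ready windows: (n_windows, C, W), labels, and provenance.

    provenance[i] = (epoch_index, window_index) of window i within its
    source epoch; every (epoch, window) pair appears exactly once.
    """

    windows: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    sampling_rate_hz: float
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.windows.ndim != 3:
            raise ValueError("windows must be 3-D (n_windows, C, W)")
        if self.labels.shape != (self.windows.shape[0],):
            raise ValueError("labels must have one entry per window")
        if self.provenance is None:
            self.provenance = np.stack(
                [np.arange(len(self.labels)), np.zeros(len(self.labels), int)],
                axis=1,
            )
        self.provenance = np.asarray(self.provenance, dtype=np.int64)
        if self.provenance.shape != (self.windows.shape[0], 2):
            raise ValueError("provenance must be (n_windows, 2)")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.windows[idx],
            self.labels[idx],
            list(self.class_names),
            self.sampling_rate_hz,
            self.provenance[idx],
        )


@dataclass(frozen=True)
class FilterSpec:
    """Notch + Butterworth band-pass settings.

    The default reproduces the 60 Hz mains notch followed by a 2-60 Hz
    order-5 Butterworth band-pass used for 160 Hz recordings.
    """

    notch_freq_hz: float | None = 60.0
    notch_q: float = 30.0
    bandpass_low_hz: float = 2.0
    bandpass_high_hz: float = 60.0
    bandpass_order: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("need 0 < bandpass_low_hz < bandpass_high_hz")
        if self.bandpass_order < 1:
            raise ValueError("bandpass_order must be >= 1")
        if self.notch_freq_hz is not None and self.notch_freq_hz <= 0:
            raise ValueError("notch_freq_hz must be positive")


def exclude_subjects(subject_ids: Sequence[int]) -> list[int]:
    """Drop the mis-annotated PhysioNet subjects; order preserved.

    IDs not in the exclusion set pass through untouched; absent excluded
    IDs are simply ignored.
    """
    return [s for s in subject_ids if s not in EEGMMIDB_EXCLUDED_SUBJECTS]


def extract_epochs(
    rec: AnnotatedRecording,
    keep_labels: Sequence[str],
    epoch_duration_s: float,
    offset_s: float = 0.0,
) -> EpochSet:
    """Clip one fixed-length epoch per kept event.

    Each epoch starts at ``onset + offset_s`` and spans ``epoch_duration_s``.
    Events whose label is not in keep_labels (e.g. rest periods) are
    skipped; events too close to the end of the record for a full epoch
    are dropped with a logged count.
    """
    fs = rec.sampling_rate_hz
    n_samp = epoch_duration_s * fs
    if abs(n_samp - round(n_samp)) > 1e-9 or round(n_samp) <= 0:
        raise ValueError(
            f"epoch_duration_s * sampling_rate ({epoch_duration_s} * {fs}) "
            "must be a positive integer number of samples"
        )
    w = int(round(n_samp))
    off = int(round(offset_s * fs))

    class_names = list(keep_labels)
    label_to_idx = {lab: i for i, lab in enumerate(class_names)}
    epochs, labels, dropped = [], [], 0
    for onset, _dur, lab in rec.events:
        if lab not in label_to_idx:
            continue
        start = onset + off
        if start < 0 or start + w > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.signal[:, start : start + w])
        labels.append(label_to_idx[lab])
    if dropped:
        logger.info("extract_epochs: dropped %d incomplete epoch(s)", dropped)
    if not epochs:
        raise ValueError(
            f"no events with labels {class_names} yielded a full epoch"
        )
    return EpochSet(np.stack(epochs), np.array(labels), class_names, fs)


def window_epochs(epochs: EpochSet, window_len: int) -> WindowedDataset:
    """Partition every epoch into consecutive non-overlapping windows.

    Each window inherits its source epoch's label. If window_len does not
    divide the epoch length the trailing remainder is dropped (logged).
    Concatenating one epoch's windows in order reconstructs the epoch
    (up to any dropped remainder).
    """
    w_epoch = epochs.epoch_len
    if window_len <= 0 or window_len > w_epoch:
        raise ValueError(
            f"window_len {window_len} must be in [1, epoch length {w_epoch}]"
        )
    n_win = w_epoch // window_len
    rem = w_epoch - n_win * window_len
    if rem:
        logger.info(
            "window_epochs: dropping %d trailing sample(s) per epoch", rem
        )
    n_ep, c, _ = epochs.epochs.shape
    trimmed = epochs.epochs[:, :, : n_win * window_len]
    # (n_ep, C, n_win, window_len) -> (n_ep, n_win, C, window_len)
    wins = trimmed.reshape(n_ep, c, n_win, window_len).transpose(0, 2, 1, 3)
    windows = wins.reshape(n_ep * n_win, c, window_len)
    labels = np.repeat(epochs.labels, n_win)
    prov = np.stack(
        [np.repeat(np.arange(n_ep), n_win), np.tile(np.arange(n_win), n_ep)],
        axis=1,
    )
    return WindowedDataset(
        windows, labels, list(epochs.class_names), epochs.sampling_rate_hz, prov
    )


def _design_filters(spec: FilterSpec, fs: float):
    nyq = fs / 2.0
    if spec.bandpass_high_hz >= nyq:
        raise ValueError(
            f"bandpass_high_hz {spec.bandpass_high_hz} must be below the "
            f"Nyquist frequency {nyq}"
        )
    notch = None
    if spec.notch_freq_hz is not None:
        if spec.notch_freq_hz >= nyq:
            raise ValueError("notch_freq_hz must be below Nyquist")
        notch = sps.iirnotch(spec.notch_freq_hz, spec.notch_q, fs=fs)
    sos = sps.butter(
        spec.bandpass_order,
        [spec.bandpass_low_hz, spec.bandpass_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    return notch, sos


def apply_filters(data, spec: FilterSpec, sampling_rate_hz: float | None = None):
    """Notch (if configured) then Butterworth band-pass, zero-phase.

    Accepts an AnnotatedRecording, an EpochSet, or a bare array whose last
    axis is time (then sampling_rate_hz is required). Filtering is applied
    per channel with forward-backward passes so epoch alignment is not
    shifted by group delay. Output shape equals input shape.
    """
    if isinstance(data, AnnotatedRecording):
        out = apply_filters(data.signal, spec, data.sampling_rate_hz)
        return AnnotatedRecording(
            out, data.sampling_rate_hz, list(data.channel_names), list(data.events)
        )
    if isinstance(data, EpochSet):
        out = apply_filters(data.epochs, spec, data.sampling_rate_hz)
        return EpochSet(
            out, data.labels.copy(), list(data.class_names), data.sampling_rate_hz
        )
    if sampling_rate_hz is None:
        raise ValueError("sampling_rate_hz is required for bare arrays")
    x = np.asarray(data, dtype=np.float64)
    notch, sos = _design_filters(spec, sampling_rate_hz)
    if notch is not None:
        b, a = notch
        x = sps.filtfilt(b, a, x, axis=-1)
    return sps.sosfiltfilt(sos, x, axis=-1)


def standardize(
    train_windows: np.ndarray, *other_windows: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Per-channel z-scoring with statistics from the training set only.

    Returns ([standardized train, standardized others...], mean, sd) where
    mean and sd are per-channel vectors computed over the training
    partition and reused verbatim for every other partition.
    """
    train = np.asarray(train_windows, dtype=np.float64)
    if train.ndim != 3 or train.shape[0] == 0:
        raise ValueError("training set must be a non-empty (N, C, W) array")
    mean = train.mean(axis=(0, 2))
    sd = train.std(axis=(0, 2))
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(
            f"zero-variance channel(s) {bad.tolist()} cannot be standardized"
        )
    out = []
    for arr in (train, *other_windows):
        arr = np.asarray(arr, dtype=np.float64)
        out.append((arr - mean[None, :, None]) / sd[None, :, None])
    return out, mean, sd


# ---------------------------------------------------------------------------
# Dataset recipes

def eegmmidb_recipe(
    rec: AnnotatedRecording,
    keep_labels: Sequence[str] = ("T1", "T2"),
    filter_spec: FilterSpec | None = None,
    epoch_duration_s: float = 4.0,
    window_len: int = 80,
) -> WindowedDataset:
    """PhysioNet motor movement/imagery recipe.

    60 Hz notch + 2-60 Hz order-5 Butterworth on the continuous signal,
    4 s epochs from each task annotation (rest T0 excluded by default),
    eight 80-sample windows per epoch at 160 Hz.
    """
    spec = filter_spec if filter_spec is not None else FilterSpec()
    filtered = apply_filters(rec, spec)
    epochs = extract_epochs(filtered, keep_labels, epoch_duration_s, 0.0)
    return window_epochs(epochs, window_len)


def bci2a_recipe(
    rec: AnnotatedRecording,
    keep_labels: Sequence[str],
    epoch_duration_s: float = 4.5,
    offset_s: float = 1.5,
) -> EpochSet:
    """Graz IV-2a recipe: 4.5 s epochs from 1.5 s after cue (1125 samples
    at 250 Hz). The source records are already 0.5-100 Hz band-limited, so
    no re-filtering; standardization happens at split time."""
    return extract_epochs(rec, keep_labels, epoch_duration_s, offset_s)


def bci2b_recipe(
    rec: AnnotatedRecording,
    keep_labels: Sequence[str],
    epoch_duration_s: float = 4.5,
    offset_s: float = 1.5,
) -> EpochSet:
    """Graz IV-2b recipe; identical segmentation to IV-2a on the 3 bipolar
    EEG channels."""
    return extract_epochs(rec, keep_labels, epoch_duration_s, offset_s)
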