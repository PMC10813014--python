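"""Digital filtering, rest trimming, overlapping windowing and splits.

The pipeline order is: zero-phase Butterworth bandpass per channel, drop
the leading rest span, cut the remainder into overlapping fixed-length
windows, stack every trial's windows into a 3-D tensor (windows x
channels x samples) with aligned movement and subject labels, then split
subject-wise so test subjects never leak into training.

With the study defaults (4 s of retained signal at 1500 Hz, 250 ms
windows overlapping by 190 ms, i.e. a 60 ms step) each trial yields 63
windows of 375 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as _sig

from .synthetic import ConfigError, EmgTrial


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass; ``order`` is the designed prototype order.

    With ``zero_phase`` the filter runs forward then backward
    (filtfilt), giving zero net group delay and the squared magnitude
    response of the prototype.
    """

    order: int = 2
    low_hz: float = 10.0
    high_hz: float = 500.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ConfigError(f"high_hz={self.high_hz} must be below fs/2={fs / 2}")
        if self.order < 1:
            raise ConfigError("order must be >= 1")


@dataclass(frozen=True)
class WindowSpec:
    window_ms: float = 250.0
    overlap_ms: float = 190.0

    def __post_init__(self):
        if not (0 <= self.overlap_ms < self.window_ms):
            raise ConfigError("need 0 <= overlap_ms < window_ms")

    @property
    def step_ms(self) -> float:
        return self.window_ms - self.overlap_ms

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))


@dataclass
class WindowedDataset:
    """3-D tensor (i windows, j channels, k samples) + aligned label vectors."""

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs: float
    window_ms: float = 250.0
    overlap_ms: float = 190.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (windows x channels x samples)")
        n = self.data.shape[0]
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels/subjects must align with data's first axis")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    def subset(self, idx) -> "WindowedDataset":
        return WindowedDataset(
            self.data[idx],
            self.labels[idx],
            self.subjects[idx],
            self.fs,
            self.window_ms,
            self.overlap_ms,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Subject-wise split: test subjects held out entirely; the rest is
    shuffled then divided (1 - val_fraction) / val_fraction."""

    train_subjects: frozenset = field(default_factory=frozenset)
    test_subjects: frozenset = field(default_factory=frozenset)
    val_fraction: float = 0.20
    shuffle_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "train_subjects", frozenset(self.train_subjects))
        object.__setattr__(self, "test_subjects", frozenset(self.test_subjects))
        if self.train_subjects & self.test_subjects:
            raise ConfigError("train and test subject sets must be disjoint")
        if not (0 < self.val_fraction < 1):
            raise ConfigError("val_fraction must be in (0, 1)")


def bandpass_filter(trial: EmgTrial, spec: FilterSpec = FilterSpec()) -> EmgTrial:
    """Filter each channel independently; shape is preserved."""
    spec.validate(trial.fs)
    if trial.n_samples < 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    sos = _sig.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=trial.fs,
        output="sos",
    )
    if spec.zero_phase:
        out = _sig.sosfiltfilt(sos, trial.signal, axis=1)
    else:
        out = _sig.sosfilt(sos, trial.signal, axis=1)
    return EmgTrial(
        signal=out,
        fs=trial.fs,
        subject_id=trial.subject_id,
        movement_id=trial.movement_id,
        trial_id=trial.trial_id,
    )


def trim_rest(trial: EmgTrial, rest_s: float = 2.0) -> EmgTrial:
    """Drop the leading ``rest_s`` seconds from every channel."""
    n_drop = int(round(rest_s * trial.fs))
    if n_drop >= trial.n_samples:
        raise ValueError("rest_s covers the whole trial; nothing would remain")
    if n_drop == 0:
        return trial
    return EmgTrial(
        signal=trial.signal[:, n_drop:],
        fs=trial.fs,
        subject_id=trial.subject_id,
        movement_id=trial.movement_id,
        trial_id=trial.trial_id,
    )


def window_count(n_samples: int, window: int, step: int) -> int:
    """floor((L - W) / step) + 1; trailing partial windows are dropped."""
    if n_samples < window:
        raise ValueError("signal shorter than one window")
    return (n_samples - window) // step + 1


def segment_windows(trial: EmgTrial, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Cut a trial into overlapping windows -> array (n, channels, W).

    Window starts advance by step = window - overlap samples; half-open
    sample intervals [start, start + W).
    """
    W = spec.window_samples(trial.fs)
    step = spec.step_samples(trial.fs)
    n = window_count(trial.n_samples, W, step)
    out = np.empty((n, trial.n_channels, W), dtype=trial.signal.dtype)
    for w in range(n):
        start = w * step
        out[w] = trial.signal[:, start : start + W]
    return out


def assemble_tensor(
    trials,
    fspec: FilterSpec = FilterSpec(),
    wspec: WindowSpec = WindowSpec(),
    rest_s: float = 2.0,
    dtype=np.float32,
) -> WindowedDataset:
    """Filter -> trim -> segment every trial and stack the windows.

    Accepts any iterable of trials; all must share fs and channel count.
    """
    chunks, labels, subjects = [], [], []
    fs = n_ch = None
    for tr in trials:
        if fs is None:
            fs, n_ch = tr.fs, tr.n_channels
        elif tr.fs != fs or tr.n_channels != n_ch:
            raise ConfigError("all trials must share fs and channel count")
        w = segment_windows(trim_rest(bandpass_filter(tr, fspec), rest_s), wspec)
        chunks.append(w.astype(dtype, copy=False))
        labels.extend([tr.movement_id] * len(w))
        subjects.extend([tr.subject_id] * len(w))
    if not chunks:
        data = np.empty((0, 0, 0), dtype=dtype)
        fs = float("nan")
    else:
        data = np.concatenate(chunks, axis=0)
    return WindowedDataset(
        data=data,
        labels=np.asarray(labels, dtype=np.int64),
        subjects=np.asarray(subjects, dtype=np.int64),
        fs=fs,
        window_ms=wspec.window_ms,
        overlap_ms=wspec.overlap_ms,
    )


def split_subjectwise(ds: WindowedDataset, spec: SplitSpec):
    """-> (train, validation, test) with no window in two outputs."""
    present = set(np.unique(ds.subjects).tolist())
    unknown = present - set(spec.train_subjects) - set(spec.test_subjects)
    if unknown:
        raise ConfigError(f"subjects {sorted(unknown)} assigned to neither split")
    test_mask = np.isin(ds.subjects, sorted(spec.test_subjects))
    pool_idx = np.flatnonzero(~test_mask)
    rng = np.random.default_rng(spec.shuffle_seed)
    pool_idx = rng.permutation(pool_idx)
    n_val = int(round(spec.val_fraction * len(pool_idx)))
    val_idx = pool_idx[:n_val]
    train_idx = pool_idx[n_val:]
    return ds.subset(train_idx), ds.subset(val_idx), ds.subset(np.flatnonzero(test_mask))


def stage_split_spec(stage: int, val_fraction: float = 0.20, shuffle_seed: int = 0) -> SplitSpec:
    """Study presets: stage 1 trains on subjects 1-8 and tests on 9;
    stage 2 trains on 1-5 and tests on 6-9."""
    if stage == 1:
        return SplitSpec(frozenset(range(1, 9)), frozenset({9}), val_fraction, shuffle_seed)
    if stage == 2:
        return SplitSpec(
            frozenset(range(1, 6)), frozenset(range(6, 10)), val_fraction, shuffle_seed
        )
    raise ConfigError("stage must be 1 or 2")


def save_windows(path, ds: WindowedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("subjects", data=ds.subjects)
        f.attrs["fs"] = ds.fs
        f.attrs["window_ms"] = ds.window_ms
        f.attrs["overlap_ms"] = ds.overlap_ms


def load_windows(path) -> WindowedDataset:
    with h5py.File(path, "r") as f:
        return WindowedDataset(
            data=f["data"][()],
            labels=f["labels"][()],
            subjects=f["subjects"][()],
            fs=float(f.attrs["fs"]),
            window_ms=float(f.attrs["window_ms"]),
            overlap_ms=float(f.attrs["overlap_ms"]),
        )
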