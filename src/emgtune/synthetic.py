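"""Synthetic surface-EMG generator.

Emulates a 9-subject upper-limb acquisition protocol: five movements
(elbow flexion/extension, finger flexion/extension, rest), four bipolar
channels over the prime movers, 1.5 kHz sampling, 20 repetitions per
movement. Each 6 s trial holds 2 s of rest followed by 4 s of movement.

The signal model is deliberately simple: a band-limited Gaussian carrier
(20-450 Hz, the band holding most sEMG energy) amplitude-modulated by a
raised-cosine envelope whose gain depends on (movement, channel), plus a
broadband noise floor. Subjects differ by a per-channel multiplicative
gain drawn once per subject, which creates a cross-subject
generalization gap without further knobs.

Every trial is a pure function of (seed, subject, movement, trial): each
trial draws from its own named substream, so any subset of the dataset
is reproducible independently of generation order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as _sig

N_MOVEMENTS = 5

#: Envelope gain per (movement, channel). Channels map to biceps brachii,
#: triceps brachii, superficial finger flexor, finger extensor; each
#: movement mainly drives its prime mover with moderate co-activation,
#: and movement 5 is rest (noise floor only).
DEFAULT_CLASS_CHANNEL_WEIGHTS = np.array(
    [
        [1.00, 0.10, 0.10, 0.10],  # elbow flexion
        [0.10, 1.00, 0.10, 0.10],  # elbow extension
        [0.10, 0.10, 1.00, 0.10],  # finger flexion
        [0.10, 0.10, 0.10, 1.00],  # finger extension
        [0.00, 0.00, 0.00, 0.00],  # rest
    ]
)


class ConfigError(ValueError):
    """Raised for invalid generator or pipeline configuration."""


@dataclass(frozen=True)
class EmgTrial:
    """One recording: ``signal`` is channels x samples (arbitrary units)."""

    signal: np.ndarray
    fs: float
    subject_id: int
    movement_id: int
    trial_id: int

    def __post_init__(self):
        sig = np.asarray(self.signal)
        if sig.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SynthConfig:
    """Study-level generator settings.

    Defaults mirror the emulated acquisition: 9 subjects, 20 trials per
    movement, 4 channels at 1500 Hz, 2 s rest + 4 s movement per trial.
    """

    n_subjects: int = 9
    n_trials_per_movement: int = 20
    n_channels: int = 4
    fs: float = 1500.0
    rest_s: float = 2.0
    movement_s: float = 4.0
    carrier_band: tuple[float, float] = (20.0, 450.0)
    class_channel_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_CHANNEL_WEIGHTS.copy()
    )
    subject_gain_sd: float = 0.1
    noise_floor_sd: float = 0.03
    ramp_s: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_trials_per_movement < 1:
            raise ConfigError("need at least one subject and one trial")
        if self.rest_s < 0 or self.movement_s <= 0:
            raise ConfigError("durations must be positive")
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.fs / 2):
            raise ConfigError("carrier_band must lie inside (0, fs/2)")
        w = np.asarray(self.class_channel_weights, dtype=float)
        if w.shape != (N_MOVEMENTS, self.n_channels):
            raise ConfigError(
                f"class_channel_weights must be {N_MOVEMENTS} x {self.n_channels}"
            )
        for a in range(N_MOVEMENTS):
            for b in range(a + 1, N_MOVEMENTS):
                if np.allclose(w[a], w[b]):
                    raise ConfigError("class_channel_weights rows must be distinct")
        if 2 * self.ramp_s > self.movement_s:
            raise ConfigError("ramps cannot exceed the movement span")

    @property
    def duration_s(self) -> float:
        return self.rest_s + self.movement_s

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.fs * self.duration_s))


def _trial_rng(cfg: SynthConfig, subject_id: int, movement_id: int, trial_id: int):
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(subject_id, movement_id, trial_id))
    return np.random.default_rng(ss)


def subject_gains(cfg: SynthConfig, subject_id: int) -> np.ndarray:
    """Per-channel multiplicative gains for one subject (log-normal)."""
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(subject_id,))
    rng = np.random.default_rng(ss)
    return np.exp(rng.normal(0.0, cfg.subject_gain_sd, size=cfg.n_channels))


def _raised_cosine_envelope(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[n - n_ramp :] = ramp[::-1]
    return env


def _bandlimited_carrier(rng, n_channels, n_samples, band, fs) -> np.ndarray:
    """Unit-RMS Gaussian noise bandpassed to ``band`` per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = _sig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = _sig.sosfiltfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
    return carrier / np.maximum(rms, 1e-30)


def generate_trial(
    cfg: SynthConfig, subject_id: int, movement_id: int, trial_id: int
) -> EmgTrial:
    """Generate one trial: rest span (noise floor) then modulated movement span.

    Deterministic given (cfg.seed, subject_id, movement_id, trial_id).
    """
    if not (1 <= movement_id <= N_MOVEMENTS):
        raise ValueError(f"movement_id must be in 1..{N_MOVEMENTS}, got {movement_id}")
    if not (1 <= subject_id <= cfg.n_subjects):
        raise ValueError(f"subject_id must be in 1..{cfg.n_subjects}")
    rng = _trial_rng(cfg, subject_id, movement_id, trial_id)

    n_rest = int(round(cfg.rest_s * cfg.fs))
    n_mov = int(round(cfg.movement_s * cfg.fs))
    n_total = cfg.samples_per_trial

    sig = rng.normal(0.0, cfg.noise_floor_sd, size=(cfg.n_channels, n_total))
    carrier = _bandlimited_carrier(rng, cfg.n_channels, n_mov, cfg.carrier_band, cfg.fs)
    env = _raised_cosine_envelope(n_mov, int(round(cfg.ramp_s * cfg.fs)))
    gains = (
        np.asarray(cfg.class_channel_weights, dtype=float)[movement_id - 1]
        * subject_gains(cfg, subject_id)
    )
    sig[:, n_rest:] += gains[:, None] * env[None, :] * carrier
    return EmgTrial(
        signal=sig,
        fs=cfg.fs,
        subject_id=subject_id,
        movement_id=movement_id,
        trial_id=trial_id,
    )


def generate_dataset(cfg: SynthConfig) -> list[EmgTrial]:
    """All (subject, movement, trial) combinations, each exactly once."""
    return [
        generate_trial(cfg, s, m, t)
        for s in range(1, cfg.n_subjects + 1)
        for m in range(1, N_MOVEMENTS + 1)
        for t in range(1, cfg.n_trials_per_movement + 1)
    ]


# ---------------------------------------------------------------------------
# Serialization


def save_trials(path, trials: list[EmgTrial]) -> None:
    """Write trials to an HDF5 container, one group per trial."""
    with h5py.File(path, "w") as f:
        for tr in trials:
            g = f.create_group(
                f"subject_{tr.subject_id:03d}/movement_{tr.movement_id}/trial_{tr.trial_id:03d}"
            )
            d = g.create_dataset("signal", data=tr.signal)
            d.attrs["fs"] = tr.fs
            d.attrs["subject_id"] = tr.subject_id
            d.attrs["movement_id"] = tr.movement_id
            d.attrs["trial_id"] = tr.trial_id


def load_trials(path) -> list[EmgTrial]:
    trials = []

    def visit(_name, obj):
        if isinstance(obj, h5py.Dataset):
            trials.append(
                EmgTrial(
                    signal=obj[()],
                    fs=float(obj.attrs["fs"]),
                    subject_id=int(obj.attrs["subject_id"]),
                    movement_id=int(obj.attrs["movement_id"]),
                    trial_id=int(obj.attrs["trial_id"]),
                )
            )

    with h5py.File(path, "r") as f:
        f.visititems(visit)
    trials.sort(key=lambda t: (t.subject_id, t.movement_id, t.trial_id))
    return trials


def save_trial_csv(path, trial: EmgTrial) -> None:
    """Plain-text export: samples x channels with a header row."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"ch{c + 1}" for c in range(trial.n_channels)])
        w.writerows(trial.signal.T.tolist())


def load_trial_csv(path, fs, subject_id=1, movement_id=1, trial_id=1) -> EmgTrial:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return EmgTrial(
        signal=np.atleast_2d(data).T,
        fs=fs,
        subject_id=subject_id,
        movement_id=movement_id,
        trial_id=trial_id,
    )
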