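"""Time-domain sEMG features and the Gaussian-kernel SVM baseline.

The baseline characterizes each window with six standard time-domain
descriptors assigned per sensor (waveform length, log detector, Shannon
entropy, myopulse percentage rate, modified mean absolute value type 1,
zero crossings) and feeds the resulting 8-vector to a one-vs-one
RBF-kernel support vector machine.

Feature definitions (x = one channel's window, length N):

* waveform_length  = sum |x[t+1] - x[t]|
* log_detector     = exp(mean(log max(|x|, eps)))
* shannon_entropy  = -sum p log2 p over a normalized histogram of |x|
* myopulse_rate    = fraction of samples with |x| >= threshold
* mmav1            = mean(w * |x|), w = 1 on the central 50% of the
                     window and 0.5 outside
* zero_crossings   = sign changes whose amplitude step exceeds a deadband
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: (sensor index, feature name) pairs; sensors are 1-based channels.
DEFAULT_ASSIGNMENTS = (
    (1, "waveform_length"),
    (2, "log_detector"),
    (3, "shannon_entropy"),
    (4, "shannon_entropy"),
    (2, "myopulse_rate"),
    (4, "myopulse_rate"),
    (3, "mmav1"),
    (3, "zero_crossings"),
)


@dataclass(frozen=True)
class FeatureRecipe:
    assignments: tuple = DEFAULT_ASSIGNMENTS
    #: per-channel |x| threshold for the myopulse rate; scalar or array
    myopulse_threshold: object = 0.05
    #: per-channel amplitude-step deadband for zero crossings
    zc_deadband: object = 0.01
    entropy_bins: int = 32
    log_eps: float = 1e-10
    mmav_low: float = 0.25
    mmav_high: float = 0.75

    def __post_init__(self):
        for sensor, name in self.assignments:
            if sensor < 1:
                raise ValueError("sensor indices are 1-based")
            if name not in _FEATURES:
                raise ValueError(f"unknown feature {name!r}")
        if np.any(np.asarray(self.myopulse_threshold) < 0) or np.any(
            np.asarray(self.zc_deadband) < 0
        ):
            raise ValueError("thresholds must be >= 0")

    def _channel_value(self, attr, channel0):
        v = np.asarray(getattr(self, attr))
        return float(v) if v.ndim == 0 else float(v[channel0])


def calibrate_recipe(recipe: FeatureRecipe, training_windows: np.ndarray) -> FeatureRecipe:
    """Set data-driven thresholds from training windows (i, ch, k):
    myopulse threshold = 1.6% of each channel's max |x|, zero-crossing
    deadband = 1% of each channel's RMS."""
    w = np.asarray(training_windows)
    max_abs = np.max(np.abs(w), axis=(0, 2))
    rms = np.sqrt(np.mean(w.astype(np.float64) ** 2, axis=(0, 2)))
    return replace(recipe, myopulse_threshold=0.016 * max_abs, zc_deadband=0.01 * rms)


def waveform_length(x, _r=None, _c=0) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(np.abs(np.diff(x))))


def log_detector(x, recipe: FeatureRecipe, _c=0) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(np.maximum(np.abs(x), recipe.log_eps)))))


def shannon_entropy(x, recipe: FeatureRecipe, _c=0) -> float:
    a = np.abs(np.asarray(x, dtype=float))
    hi = a.max()
    if hi == 0:
        return 0.0
    counts, _ = np.histogram(a, bins=recipe.entropy_bins, range=(0.0, hi))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def myopulse_rate(x, recipe: FeatureRecipe, channel0=0) -> float:
    thr = recipe._channel_value("myopulse_threshold", channel0)
    x = np.asarray(x, dtype=float)
    return float(np.mean(np.abs(x) >= thr))


def mmav1(x, recipe: FeatureRecipe, _c=0) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = np.full(n, 0.5)
    lo = int(np.floor(recipe.mmav_low * n))
    hi = int(np.floor(recipe.mmav_high * n))
    w[lo:hi] = 1.0
    return float(np.mean(w * np.abs(x)))


def zero_crossings(x, recipe: FeatureRecipe, channel0=0) -> float:
    dead = recipe._channel_value("zc_deadband", channel0)
    x = np.asarray(x, dtype=float)
    sign_change = x[:-1] * x[1:] < 0
    big_step = np.abs(np.diff(x)) >= dead
    return float(np.sum(sign_change & big_step))


_FEATURES = {
    "waveform_length": waveform_length,
    "log_detector": log_detector,
    "shannon_entropy": shannon_entropy,
    "myopulse_rate": myopulse_rate,
    "mmav1": mmav1,
    "zero_crossings": zero_crossings,
}


def extract_features(window: np.ndarray, recipe: FeatureRecipe = FeatureRecipe()) -> np.ndarray:
    """One value per (sensor, feature) assignment, in recipe order."""
    window = np.asarray(window)
    if window.ndim != 2 or window.shape[1] == 0:
        raise ValueError("window must be a non-empty channels x samples array")
    out = np.empty(len(recipe.assignments))
    for q, (sensor, name) in enumerate(recipe.assignments):
        if sensor > window.shape[0]:
            raise ValueError(f"recipe references sensor {sensor} but window has "
                             f"{window.shape[0]} channels")
        out[q] = _FEATURES[name](window[sensor - 1], recipe, sensor - 1)
    return out


def extract_feature_matrix(windows: np.ndarray, recipe: FeatureRecipe = FeatureRecipe()):
    """Stack :func:`extract_features` over a (i, ch, k) tensor -> (i, n_feat)."""
    windows = np.asarray(windows)
    return np.stack([extract_features(w, recipe) for w in windows])


def save_feature_matrix(path, features: np.ndarray, labels, recipe: FeatureRecipe) -> None:
    header = [f"ch{s}_{n}" for s, n in recipe.assignments] + ["label"]
    table = np.column_stack([features, np.asarray(labels)])
    np.savetxt(path, table, delimiter=",", header=",".join(header), comments="")


def train_svm_baseline(
    train_features,
    train_labels,
    C: float = 10.0,
    gamma="scale",
    seed: int = 0,
) -> Pipeline:
    """Standardized one-vs-one RBF SVM over feature vectors."""
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train the SVM baseline")
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)),
        ]
    )
    clf.fit(np.asarray(train_features), y)
    return clf


def fit_svm_with_grid(
    train_features,
    train_labels,
    val_features,
    val_labels,
    C_grid=(1.0, 10.0, 100.0),
    gamma_grid=("scale", 0.1, 1.0),
    seed: int = 0,
):
    """Pick (C, gamma) by validation accuracy; returns (model, best pair)."""
    best, best_acc = None, -1.0
    for C in C_grid:
        for gamma in gamma_grid:
            model = train_svm_baseline(train_features, train_labels, C=C, gamma=gamma, seed=seed)
            acc = float(np.mean(model.predict(val_features) == np.asarray(val_labels)))
            if acc > best_acc:
                best, best_acc, best_pair = model, acc, (C, gamma)
    return best, best_pair
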