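import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sig

import emgtune as et
from emgtune.preprocessing import window_count
from emgtune.synthetic import ConfigError


def _trial(x, fs=1500.0, **ids):
    defaults = dict(subject_id=1, movement_id=1, trial_id=1)
    defaults.update(ids)
    return et.EmgTrial(signal=np.atleast_2d(x), fs=fs, **defaults)


# ---------------------------------------------------------------------------
# bandpass_filter


def test_filter_zero_in_zero_out():
    out = et.bandpass_filter(_trial(np.zeros((4, 3000))))
    assert np.allclose(out.signal, 0.0)


@pytest.mark.parametrize(
    "freq,check",
    [
        (100.0, lambda amp, h2: amp == pytest.approx(1.0, abs=0.01)),
        (2.0, lambda amp, h2: amp < 0.1),
    ],
)
def test_filter_sine_amplitude_matches_squared_response(freq, check):
    """Steady-state gain equals the designed prototype's |H|^2 (the
    forward-backward application squares the magnitude response)."""
    fs = 1500.0
    t = np.arange(0, 10, 1 / fs)
    out = et.bandpass_filter(_trial(np.sin(2 * np.pi * freq * t), fs=fs)).signal[0]
    mid = out[len(t) // 4 : 3 * len(t) // 4]
    amp = (mid.max() - mid.min()) / 2
    sos = sig.butter(2, [10, 500], btype="bandpass", fs=fs, output="sos")
    _, h = sig.sosfreqz(sos, worN=[2 * np.pi * freq / fs])
    h2 = abs(h[0]) ** 2
    assert amp == pytest.approx(h2, rel=0.02)
    assert check(amp, h2)


def test_filter_rejects_bad_corner():
    with pytest.raises(ConfigError):
        et.bandpass_filter(_trial(np.zeros(2000)), et.FilterSpec(high_hz=800.0))


def test_zero_phase_preserves_palindrome_symmetry():
    # edge-tapered palindromic input -> palindromic output
    t = np.linspace(0, 1, 3000)
    half = np.sin(2 * np.pi * 40 * t) * np.hanning(3000)
    x = np.concatenate([half, half[::-1]])
    y = et.bandpass_filter(_trial(x)).signal[0]
    assert np.max(np.abs(y - y[::-1])) < 1e-3 * np.max(np.abs(y))


def test_filter_commutes_with_channel_permutation():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((4, 2000))
    perm = [2, 0, 3, 1]
    a = et.bandpass_filter(_trial(x)).signal[perm]
    b = et.bandpass_filter(_trial(x[perm])).signal
    np.testing.assert_allclose(a, b, rtol=1e-12)


# ---------------------------------------------------------------------------
# trim_rest / segment_windows


def test_trim_rest_drops_leading_samples():
    x = np.arange(9000, dtype=float).reshape(1, -1)
    out = et.trim_rest(_trial(x), rest_s=2.0)
    assert out.n_samples == 6000
    assert out.signal[0, 0] == 3000.0
    assert et.trim_rest(_trial(x), rest_s=0.0).n_samples == 9000
    with pytest.raises(ValueError):
        et.trim_rest(_trial(x), rest_s=6.0)


def test_study_windowing_counts():
    # 4 s at 1.5 kHz, 250/190 ms -> 63 windows of 375 samples
    w = et.segment_windows(_trial(np.zeros((4, 6000))))
    assert w.shape == (63, 4, 375)
    spec = et.WindowSpec()
    assert spec.window_samples(1500.0) == 375
    assert spec.step_samples(1500.0) == 90


def test_single_window_when_exact_fit():
    w = et.segment_windows(_trial(np.zeros((2, 375))))
    assert w.shape == (1, 2, 375)
    with pytest.raises(ValueError):
        et.segment_windows(_trial(np.zeros((2, 374))))


def test_window_count_against_enumeration_example():
    # L=1000, W=375, step=90 -> starts 0, 90, ..., 625 is not reachable;
    # brute-force enumeration of valid offsets
    starts = [s for s in range(0, 1000 - 375 + 1, 90)]
    assert window_count(1000, 375, 90) == len(starts) == 7


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    L=st.integers(min_value=1, max_value=5000),
    W=st.integers(min_value=1, max_value=5000),
    step=st.integers(min_value=1, max_value=600),
)
def test_window_count_formula_matches_enumeration(L, W, step):
    if L < W:
        with pytest.raises(ValueError):
            window_count(L, W, step)
    else:
        assert window_count(L, W, step) == len(range(0, L - W + 1, step))


def test_windows_are_half_open_slices():
    x = np.arange(6000, dtype=float).reshape(1, -1)
    w = et.segment_windows(_trial(x))
    np.testing.assert_array_equal(w[0, 0], x[0, :375])
    np.testing.assert_array_equal(w[1, 0], x[0, 90 : 90 + 375])


def test_window_spec_validation():
    with pytest.raises(ConfigError):
        et.WindowSpec(window_ms=250, overlap_ms=250)


# ---------------------------------------------------------------------------
# assemble_tensor


def test_assemble_single_trial_yields_63_windows(tiny_trials):
    ds = et.assemble_tensor(tiny_trials[:1])
    assert ds.data.shape == (63, 4, 375)
    assert np.all(ds.labels == tiny_trials[0].movement_id)
    assert np.all(ds.subjects == tiny_trials[0].subject_id)


def test_assemble_empty_list_gives_empty_dataset():
    ds = et.assemble_tensor([])
    assert ds.n_windows == 0


def test_assemble_rejects_heterogeneous_trials(tiny_trials):
    odd = et.EmgTrial(signal=np.zeros((3, 9000)), fs=1500.0,
                      subject_id=1, movement_id=1, trial_id=99)
    with pytest.raises(ConfigError):
        et.assemble_tensor([tiny_trials[0], odd])


def test_assemble_label_alignment(tiny_windows, tiny_trials):
    assert tiny_windows.n_windows == len(tiny_trials) * 63
    # block structure: trial order preserved, 63 windows per trial
    assert np.all(tiny_windows.labels[:63] == tiny_trials[0].movement_id)


# ---------------------------------------------------------------------------
# split_subjectwise


def test_split_partitions_windows(tiny_windows):
    spec = et.SplitSpec(train_subjects={1}, test_subjects={2}, shuffle_seed=4)
    train, val, test = et.split_subjectwise(tiny_windows, spec)
    assert train.n_windows + val.n_windows + test.n_windows == tiny_windows.n_windows
    assert set(np.unique(test.subjects)) == {2}
    assert 2 not in set(np.unique(train.subjects)) | set(np.unique(val.subjects))
    # 80/20 within the training pool (+-1 window)
    pool = train.n_windows + val.n_windows
    assert abs(val.n_windows - round(0.2 * pool)) <= 1


def test_split_fraction_arithmetic():
    # 100 non-test windows at val_fraction 0.2 -> exactly 20 validation
    data = np.zeros((120, 2, 5), dtype=np.float32)
    subjects = np.array([1] * 100 + [2] * 20)
    labels = np.tile(np.arange(1, 6), 24)
    ds = et.WindowedDataset(data, labels, subjects, fs=1500.0)
    train, val, test = et.split_subjectwise(
        ds, et.SplitSpec(train_subjects={1}, test_subjects={2}, shuffle_seed=0)
    )
    assert (train.n_windows, val.n_windows, test.n_windows) == (80, 20, 20)


def test_split_rejects_bad_subject_sets(tiny_windows):
    with pytest.raises(ConfigError):
        et.SplitSpec(train_subjects={1, 2}, test_subjects={2})
    with pytest.raises(ConfigError):
        et.split_subjectwise(
            tiny_windows, et.SplitSpec(train_subjects={1}, test_subjects={3})
        )


def test_split_is_seeded(tiny_windows):
    spec = et.SplitSpec(train_subjects={1}, test_subjects={2}, shuffle_seed=11)
    a = et.split_subjectwise(tiny_windows, spec)
    b = et.split_subjectwise(tiny_windows, spec)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.labels, y.labels)
        np.testing.assert_array_equal(x.data, y.data)


def test_stage_presets():
    s1 = et.stage_split_spec(1)
    assert s1.train_subjects == frozenset(range(1, 9))
    assert s1.test_subjects == frozenset({9})
    s2 = et.stage_split_spec(2)
    assert s2.train_subjects == frozenset(range(1, 6))
    assert s2.test_subjects == frozenset(range(6, 10))


def test_windows_h5_round_trip(tmp_path, tiny_windows):
    path = tmp_path / "w.h5"
    et.preprocessing.save_windows(path, tiny_windows)
    back = et.preprocessing.load_windows(path)
    np.testing.assert_array_equal(back.data, tiny_windows.data)
    np.testing.assert_array_equal(back.labels, tiny_windows.labels)
    assert back.fs == tiny_windows.fs
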