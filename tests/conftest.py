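import numpy as np
import pytest

import emgtune as et


@pytest.fixture(scope="session")
def tiny_cfg():
    # 2 subjects x 5 movements x 2 trials: enough structure, fast to build
    return et.SynthConfig(n_subjects=2, n_trials_per_movement=2, seed=123)


@pytest.fixture(scope="session")
def tiny_trials(tiny_cfg):
    return et.generate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_windows(tiny_trials):
    return et.assemble_tensor(tiny_trials)


@pytest.fixture(scope="session")
def study_fixture():
    """The scaled-down study dataset: 4 subjects (3 train / 1 held out),
    5 trials per movement, default generator settings."""
    cfg = et.SynthConfig(n_subjects=4, n_trials_per_movement=5, seed=0)
    ds = et.assemble_tensor(et.generate_dataset(cfg))
    split = et.SplitSpec(train_subjects={1, 2, 3}, test_subjects={4}, shuffle_seed=0)
    train, val, test = et.split_subjectwise(ds, split)

    def pack(d):
        return et.windows_to_sequences(d.data), d.labels

    return {"train": pack(train), "val": pack(val), "test": pack(test),
            "raw": (train, val, test)}


@pytest.fixture(scope="session")
def toy_sequences():
    """200 trivially separable 2-class sequences (constant-sign patterns)."""
    rng = np.random.default_rng(7)
    n, T, F = 200, 3, 8
    labels = np.repeat([1, 2], n // 2)
    x = rng.normal(0, 0.1, size=(n, T, F))
    x[labels == 1] += 1.0
    x[labels == 2] -= 1.0
    perm = rng.permutation(n)
    return x[perm], labels[perm]
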