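import numpy as np
import pytest

import emgtune.rnn as rnn


def _spec(**kw):
    base = dict(arch="lstm", n1=3, n2=4, input_timesteps=3, input_features=6,
                n_classes=3, normalize_input=False, lr=1e-3)
    base.update(kw)
    return rnn.ModelSpec(**base)


# ---------------------------------------------------------------------------
# parameter counting


@pytest.mark.parametrize(
    "arch,n1,n2,norm,expected",
    [
        ("lstm", 28, 74, True, 76_861),
        ("gru", 25, 18, True, 33_425),
        ("bidirectional", 14, 13, False, 48_183),
    ],
)
def test_study_parameter_counts(arch, n1, n2, norm, expected):
    spec = rnn.ModelSpec(arch=arch, n1=n1, n2=n2, normalize_input=norm)
    assert rnn.count_trainable_params(spec) == expected
    assert rnn.build_model(spec).n_params() == expected


def test_minimal_lstm_count_hand_expansion():
    # one unit per layer, one input feature, two classes, no normalization:
    # 4*(1*(1+1)+1) + 4*(1*(1+1)+1) + (1+1)*2 = 12 + 12 + 4 = 28
    spec = rnn.ModelSpec(arch="lstm", n1=1, n2=1, input_features=1,
                         input_timesteps=2, n_classes=2, normalize_input=False)
    assert rnn.count_trainable_params(spec) == 28


def test_counter_matches_introspection_on_randomized_specs():
    rng = np.random.default_rng(0)
    for _ in range(50):
        spec = rnn.ModelSpec(
            arch=rng.choice(rnn.ARCHITECTURES),
            n1=int(rng.integers(1, 12)),
            n2=int(rng.integers(1, 12)),
            input_timesteps=int(rng.integers(1, 5)),
            input_features=int(rng.integers(1, 40)),
            n_classes=int(rng.integers(2, 7)),
            normalize_input=bool(rng.integers(0, 2)),
        )
        assert rnn.count_trainable_params(spec) == rnn.build_model(spec).n_params()


# ---------------------------------------------------------------------------
# forward contracts


def test_softmax_output_valid():
    model = rnn.build_model(_spec(n_classes=5, normalize_input=True), seed=0)
    x = np.random.default_rng(1).standard_normal((7, 3, 6))
    probs = model.forward(x)
    assert probs.shape == (7, 5)
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_bidirectional_second_layer_sees_doubled_features():
    spec = rnn.ModelSpec(arch="bidirectional", n1=14, n2=13, normalize_input=False)
    model = rnn.build_model(spec)
    layer2 = model.layers[1]
    assert layer2.fwd.W.shape[0] == 28  # 2 x 14 concatenated features


def test_predict_labels_and_tie_break():
    spec = _spec(n_classes=4)
    model = rnn.build_model(spec, seed=0)
    x = np.random.default_rng(2).standard_normal((5, 3, 6))
    labels = rnn.predict(model, x)
    assert labels.shape == (5,)
    assert np.all((labels >= 1) & (labels <= 4))
    # degenerate head -> uniform softmax -> lowest class wins
    model.set_param(f"layer{len(model.layers) - 1}.W", np.zeros_like(model.layers[-1].W))
    model.set_param(f"layer{len(model.layers) - 1}.b", np.zeros_like(model.layers[-1].b))
    assert np.all(rnn.predict(model, x) == 1)


def test_layout_mismatch_rejected():
    model = rnn.build_model(_spec())
    with pytest.raises(ValueError):
        model.forward(np.zeros((2, 4, 6)))


def test_single_window_promotion():
    model = rnn.build_model(_spec())
    assert rnn.predict(model, np.zeros((3, 6))).shape == (1,)


def test_windows_to_sequences_layouts():
    data = np.arange(24).reshape(2, 3, 4)
    np.testing.assert_array_equal(rnn.windows_to_sequences(data), data)
    np.testing.assert_array_equal(
        rnn.windows_to_sequences(data, "samples_as_steps"), data.transpose(0, 2, 1)
    )
    with pytest.raises(ValueError):
        rnn.windows_to_sequences(data, "nope")


# ---------------------------------------------------------------------------
# gradients vs central finite differences


@pytest.mark.parametrize(
    "arch,norm",
    [("lstm", True), ("gru", True), ("bidirectional", False)],
)
def test_backprop_matches_finite_differences(arch, norm):
    spec = _spec(arch=arch, normalize_input=norm)
    model = rnn.build_model(spec, seed=1)
    rng = np.random.default_rng(3)
    x = rng.standard_normal((4, 3, 6))
    y = rnn.one_hot(rng.integers(1, 4, 4), 3)
    _, grads, _ = model.loss_and_grads(x, y)
    check_rng = np.random.default_rng(5)
    for name, arr in model.named_params():
        for fi in check_rng.choice(arr.size, size=min(8, arr.size), replace=False):
            mi = np.unravel_index(fi, arr.shape)
            eps, orig = 1e-6, arr[mi]
            arr[mi] = orig + eps
            lp, _, _ = model.loss_and_grads(x, y)
            arr[mi] = orig - eps
            lm, _, _ = model.loss_and_grads(x, y)
            arr[mi] = orig
            fd = (lp - lm) / (2 * eps)
            assert grads[name][mi] == pytest.approx(fd, rel=1e-4, abs=1e-8), name


# ---------------------------------------------------------------------------
# training


def test_train_learns_separable_toy(toy_sequences):
    x, y = toy_sequences
    spec = rnn.ModelSpec(arch="lstm", n1=4, n2=4, input_timesteps=3,
                         input_features=8, n_classes=2, normalize_input=False,
                         lr=0.02)
    model = rnn.build_model(spec, seed=0)
    res = rnn.train(model, spec, (x[:160], y[:160]), (x[160:], y[160:]),
                    rnn.TrainConfig(batch_size=32, max_epochs=15, seed=0))
    assert res.final_train_accuracy == 1.0
    assert res.best_val_accuracy == 1.0


def test_early_stop_after_patience_without_improvement(toy_sequences):
    # a vanishing learning rate freezes the model, so validation accuracy
    # is constant from epoch 1 and training stops at 1 + patience
    x, y = toy_sequences
    spec = rnn.ModelSpec(arch="gru", n1=2, n2=2, input_timesteps=3,
                         input_features=8, n_classes=2, normalize_input=False,
                         lr=1e-30)
    model = rnn.build_model(spec, seed=0)
    res = rnn.train(model, spec, (x[:64], y[:64]), (x[64:96], y[64:96]),
                    rnn.TrainConfig(batch_size=16, max_epochs=20, patience=3, seed=0))
    assert res.effective_epochs == 1 + 3
    assert len(res.history["val_accuracy"]) == res.effective_epochs


def test_single_epoch_budget(toy_sequences):
    x, y = toy_sequences
    spec = rnn.ModelSpec(arch="lstm", n1=2, n2=2, input_timesteps=3,
                         input_features=8, n_classes=2, normalize_input=False, lr=1e-3)
    model = rnn.build_model(spec, seed=0)
    res = rnn.train(model, spec, (x[:64], y[:64]), (x[64:96], y[64:96]),
                    rnn.TrainConfig(batch_size=16, max_epochs=1, seed=0))
    assert res.effective_epochs == 1


def test_training_reproducible(toy_sequences):
    x, y = toy_sequences
    spec = rnn.ModelSpec(arch="gru", n1=3, n2=3, input_timesteps=3,
                         input_features=8, n_classes=2, normalize_input=False, lr=5e-3)
    histories = []
    for _ in range(2):
        model = rnn.build_model(spec, seed=4)
        res = rnn.train(model, spec, (x[:128], y[:128]), (x[128:], y[128:]),
                        rnn.TrainConfig(batch_size=32, max_epochs=4, seed=4))
        histories.append(res.history)
    assert histories[0] == histories[1]


def test_empty_training_set_rejected(toy_sequences):
    x, y = toy_sequences
    spec = rnn.ModelSpec(arch="lstm", n1=2, n2=2, input_timesteps=3,
                         input_features=8, n_classes=2, normalize_input=False, lr=1e-3)
    model = rnn.build_model(spec)
    with pytest.raises(ValueError):
        rnn.train(model, spec, (x[:0], y[:0]), (x[:8], y[:8]),
                  rnn.TrainConfig(batch_size=4, max_epochs=1, seed=0))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        rnn.ModelSpec(arch="transformer")
    with pytest.raises(ValueError):
        rnn.ModelSpec(lr=0.0)
    with pytest.raises(ValueError):
        rnn.TrainConfig(batch_size=0)


def test_summary_mentions_total():
    spec = rnn.ModelSpec(arch="lstm", n1=28, n2=74, normalize_input=True)
    text = rnn.summary(spec)
    assert "76861" in text
    assert "LSTM(28" in text
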