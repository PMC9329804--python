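"""Architecture accounting, augmentation bookkeeping, and training
mechanics of the compact motor-imagery CNN."""

import numpy as np
import pytest

import mifatigue as mf
from mifatigue import nn
from conftest import make_epochset


# ----------------------------------------------------------- architecture

def test_layer_table_shapes_and_parameter_counts():
    model = mf.build_mi_cnn(seed=0)
    counts = mf.verify_architecture(model)
    assert counts["conv1"] == 400
    assert counts["conv2"] == 11296
    assert counts["conv3"] == 10272
    assert counts["dense"] == 2050


def test_forward_shape_chain():
    model = mf.build_mi_cnn(seed=0)
    x = np.zeros((1, 1, 32, 512), dtype=np.float32)
    shapes = []
    for layer in model.layers:
        x = layer.forward(x, training=False)
        shapes.append(x.shape[1:])
    assert shapes[0] == (16, 32, 256)          # conv1
    assert shapes[3] == (32, 16, 256)          # conv2
    assert shapes[6] == (32, 8, 64)            # pool1
    assert shapes[8] == (32, 4, 64)            # conv3
    assert shapes[11] == (32, 2, 16)           # pool2
    assert shapes[13] == (1024,)               # flatten
    assert shapes[14] == (2,)                  # dense


def test_wrong_padding_detected():
    model = mf.build_mi_cnn(seed=0)
    model.layers[0].padding = (0, 0)           # break conv1
    with pytest.raises(mf.ArchitectureError, match="conv1"):
        mf.verify_architecture(model)


# ------------------------------------------------------------ augmentation

def _trial(fs=1024.0, n_ch=4, dur=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_ch, int(dur * fs))).astype(np.float32)


def test_augment_yields_twelve_samples():
    samples = mf.augment(_trial(), 1024.0, mf.LEFT, trial=0)
    assert len(samples) == 12
    assert all(s.data.shape == (4, 512) for s in samples)


def test_phase_zero_sample_is_strided_window():
    data = _trial()
    samples = mf.augment(data, 1024.0, mf.LEFT, trial=0,
                         apply_standardize=False)
    first = samples[0]
    assert first.phase == 0 and first.window_start_s == 0.0
    np.testing.assert_array_equal(first.data, data[:, :2048][:, ::4])


def test_decimated_samples_contain_only_original_points():
    data = np.arange(2 * 5120, dtype=np.float32).reshape(2, 5120)
    for s in mf.augment(data, 1024.0, mf.LEFT, trial=0,
                        apply_standardize=False):
        assert np.isin(s.data, data).all()


def test_short_epoch_rejected():
    with pytest.raises(mf.ConfigurationError):
        mf.augment(_trial(dur=3.0), 1024.0, mf.LEFT, trial=0)


def test_dataset_counts_twelve_per_trial():
    ep = make_epochset(np.stack([_trial(n_ch=32, seed=i) for i in range(8)]),
                       1024.0, mf.CHANNEL_ORDER_32)
    X, y, groups = mf.make_dataset(ep)
    assert X.shape == (96, 1, 32, 512)
    assert np.bincount(groups).tolist() == [12] * 8
    assert set(y) == {0, 1}


# ----------------------------------------------------------- standardizing

def test_standardize_zero_mean_unit_sd():
    rng = np.random.default_rng(0)
    z = mf.standardize(5.0 + 2.0 * rng.standard_normal((32, 512)))
    assert abs(z.mean()) < 1e-6
    assert abs(z.std() - 1.0) < 1e-6


def test_standardize_idempotent_and_affine_invariant():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((8, 64))
    z = mf.standardize(x)
    np.testing.assert_allclose(mf.standardize(z), z, atol=1e-6)
    np.testing.assert_allclose(mf.standardize(3.0 * x + 7.0), z, atol=1e-5)


def test_standardize_constant_rejected():
    with pytest.raises(mf.DegenerateSignalError):
        mf.standardize(np.full((4, 4), 3.0))


# ------------------------------------------------------------- rearranging

def _identity_epochs(labels):
    """One trial whose channel c is constant c, to track permutations."""
    data = np.tile(np.arange(len(labels), dtype=np.float32)[None, :, None],
                   (2, 1, 8))
    return make_epochset(data, 1024.0, labels)


def test_rearrange_identity_and_inverse():
    ep = _identity_epochs(mf.CHANNEL_ORDER_32)
    out = mf.rearrange(ep, mf.CHANNEL_ORDER_32)
    np.testing.assert_array_equal(out.data, ep.data)
    shuffled = tuple(reversed(mf.CHANNEL_ORDER_32))
    back = mf.rearrange(mf.rearrange(ep, shuffled), mf.CHANNEL_ORDER_32)
    np.testing.assert_array_equal(back.data, ep.data)


def test_rearrange_puts_c3_in_row_eight():
    perm = tuple(sorted(mf.CHANNEL_ORDER_32))
    ep = _identity_epochs(perm)
    out = mf.rearrange(ep)
    # row 8 (index 7) of the target order is C3
    assert mf.CHANNEL_ORDER_32[7] == "C3"
    assert out.data[0, 7, 0] == perm.index("C3")


def test_rearrange_missing_channel_named():
    ep = _identity_epochs(mf.CHANNEL_ORDER_32[:-1] + ("Oz",))
    with pytest.raises(mf.ConfigurationError, match="P6"):
        mf.rearrange(ep)


# ------------------------------------------------------------------ split

def test_split_is_trial_grouped_and_sized():
    groups = np.repeat(np.arange(160), 12)
    y = np.repeat(np.arange(160) % 2, 12).astype(np.int64)
    tr, te = mf.split_train_test(y, groups, 0.8, seed=0)
    assert tr.size == 1536 and te.size == 384
    assert set(groups[tr]) & set(groups[te]) == set()
    # stratified: both classes equally represented in the test trials
    test_trials = np.unique(groups[te])
    assert (test_trials % 2 == 0).sum() == (test_trials % 2 == 1).sum()


def test_split_deterministic_per_seed():
    groups = np.repeat(np.arange(20), 12)
    y = np.repeat(np.arange(20) % 2, 12).astype(np.int64)
    a = mf.split_train_test(y, groups, 0.8, seed=5)
    b = mf.split_train_test(y, groups, 0.8, seed=5)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = mf.split_train_test(y, groups, 0.8, seed=6)
    assert not np.array_equal(a[0], c[0])


# --------------------------------------------------------------- gradients

def _numeric_grad(f, param, eps=1e-2):
    g = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = param[i]
        param[i] = old + eps
        hi = f()
        param[i] = old - eps
        lo = f()
        param[i] = old
        g[i] = (hi - lo) / (2 * eps)
    return g


def test_backward_matches_finite_differences():
    """Analytic gradients of a small conv net agree with central
    differences on every trainable parameter."""
    rng = np.random.default_rng(0)
    model = nn.Sequential([
        nn.Conv2d(1, 2, (2, 3), stride=(1, 2), padding=(0, 1), rng=rng),
        nn.BatchNorm2d(2),
        nn.ELU(),
        nn.AvgPool2d((1, 2)),
        nn.Flatten(),
        nn.Linear(2 * 3 * 4, 2, rng=rng),
    ])
    X = rng.standard_normal((5, 1, 4, 16)).astype(np.float32)
    y = np.array([0, 1, 0, 1, 1])

    def loss():
        logits = model.forward(X, training=True)
        return nn.softmax_cross_entropy(logits, y)[0]

    logits = model.forward(X, training=True)
    _, grad = nn.softmax_cross_entropy(logits, y)
    model.backward(grad)
    for param, analytic in model.parameters():
        numeric = _numeric_grad(loss, param)
        np.testing.assert_allclose(analytic, numeric, atol=5e-3)


# ---------------------------------------------------------------- training

def test_training_is_deterministic():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((24, 1, 32, 512)).astype(np.float32)
    y = (np.arange(24) % 2).astype(np.int64)

    def run():
        model = mf.build_mi_cnn(seed=3)
        rep = mf.train(model, X, y, mf.TrainConfig(epochs=2, batch_size=12,
                                                   seed=3))
        return rep.train_loss[-1]

    assert run() == run()
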