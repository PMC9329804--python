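"""Compact CNN for left/right motor-imagery classification.

The network (an EEGNet-style design with three convolutions, two
average-pooling stages and one dense layer) consumes samples of shape
``1 x 32 x 512``: 32 spatially reordered channels by 512 time points.
The reference layer table it must reproduce exactly:

    input                1 x 32 x 512
    conv1   16 maps, kernel 1x24, stride 1x2, pad 0x11 -> 32 x 256 (400 params)
    bn + ELU
    conv2   32 maps, kernel 2x11, stride 2x1, pad 0x5  -> 16 x 256 (11,296)
    bn + ELU, avg-pool 2x4 -> 8 x 64, spatial dropout 0.25
    conv3   32 maps, kernel 2x5,  stride 2x1, pad 0x2  -> 4 x 64  (10,272)
    bn + ELU, avg-pool 2x4 -> 2 x 16, spatial dropout 0.25
    flatten -> 1,024
    dense   -> 2 logits (2,050), softmax

Construction verifies every shape and the four weight counts and raises
on the first inconsistent layer.

Sample preparation: each trial epoch is cut into three 2 s windows
(starting at 0, 1 and 2 s) and each window decimated by 4 at the four
possible phases, yielding 12 samples of 512 points per trial — only
original data points, no interpolation.  Every sample is standardized
as a whole to zero mean and unit standard deviation.  Train/test
splitting groups all 12 children of a trial on one side and is
stratified by class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, LEFT, RIGHT
from .errors import (ArchitectureError, ConfigurationError,
                     DegenerateSignalError, TrainingDivergedError)
from .montage import CHANNEL_ORDER_32
from . import nn

LABEL_TO_INT = {LEFT: 0, RIGHT: 1}

#: (name, maps, (h, w) after the layer, trainable weight count) — the
#: weight counts cover the convolution/dense weights + biases.
REFERENCE_TABLE = (
    ("input", 1, (32, 512), 0),
    ("conv1", 16, (32, 256), 400),
    ("conv2", 32, (16, 256), 11296),
    ("pool1", 32, (8, 64), 0),
    ("conv3", 32, (4, 64), 10272),
    ("pool2", 32, (2, 16), 0),
    ("flatten", None, (1024,), 0),
    ("dense", None, (2,), 2050),
)


@dataclass(frozen=True)
class Sample:
    """One augmented CNN input with its provenance."""

    data: np.ndarray            # (channels, 512), standardized
    label: str
    trial: int
    window_start_s: float
    phase: int


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0
    shuffle: bool = True


@dataclass
class TrainingReport:
    train_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    best_accuracy: float = 0.0
    n_train: int = 0
    n_test: int = 0
    seed: int = 0
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 64


# ------------------------------------------------------------ preparation

def rearrange(epochs: EpochSet, order=CHANNEL_ORDER_32) -> EpochSet:
    """Reorder the channel axis to the spatial CNN order."""
    order = tuple(order)
    missing = [ch for ch in order if ch not in epochs.labels]
    if missing:
        raise ConfigurationError(f"channels missing from epochs: {missing}")
    idx = [epochs.labels.index(ch) for ch in order]
    return EpochSet(
        data=epochs.data[:, idx, :], fs=epochs.fs, labels=order,
        classes=epochs.classes, window=epochs.window,
        baseline_window=epochs.baseline_window,
        trial_order=epochs.trial_order.copy(),
        trial_ids=epochs.trial_ids.copy(),
    )


def standardize(sample: np.ndarray) -> np.ndarray:
    """Whole-sample z-scoring: subtract the global mean, divide by SD."""
    sample = np.asarray(sample, dtype=np.float64)
    sd = sample.std()
    if sd == 0:
        raise DegenerateSignalError("constant sample cannot be standardized")
    return ((sample - sample.mean()) / sd).astype(np.float32)


def augment(epoch_data: np.ndarray, fs: float, label: str, trial: int,
            window_s: float = 2.0, starts_s: tuple[float, ...] = (0.0, 1.0, 2.0),
            decim: int = 4, apply_standardize: bool = True) -> list[Sample]:
    """Sliding-window + decimation-phase augmentation of one trial.

    Each of the ``len(starts_s)`` windows of ``window_s`` seconds is
    decimated by ``decim`` at every phase offset, producing
    ``len(starts_s) * decim`` samples containing only original points.
    """
    win = int(round(window_s * fs))
    n = epoch_data.shape[1]
    last = int(round(max(starts_s) * fs)) + win
    if last > n:
        raise ConfigurationError(
            f"epoch of {n} samples too short for window ending at {last}"
        )
    out = []
    for s in starts_s:
        s0 = int(round(s * fs))
        seg = epoch_data[:, s0 : s0 + win]
        for phase in range(decim):
            sub = seg[:, phase::decim]
            data = standardize(sub) if apply_standardize else \
                sub.astype(np.float32)
            out.append(Sample(data=data, label=label, trial=trial,
                              window_start_s=float(s), phase=phase))
    return out


def make_dataset(epochs: EpochSet, order=CHANNEL_ORDER_32,
                 window_s: float = 2.0,
                 starts_s: tuple[float, ...] = (0.0, 1.0, 2.0),
                 decim: int = 4
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rearrange, augment and stack a whole EpochSet.

    Returns ``X`` of shape ``(n_samples, 1, n_channels, points)``,
    integer labels ``y`` (left=0, right=1) and the parent-trial id of
    every sample (``groups``).
    """
    ordered = rearrange(epochs, order)
    xs, ys, gs = [], [], []
    for i in range(ordered.n_trials):
        samples = augment(ordered.data[i], ordered.fs,
                          label=ordered.classes[i],
                          trial=int(ordered.trial_ids[i]),
                          window_s=window_s, starts_s=starts_s, decim=decim)
        for s in samples:
            xs.append(s.data)
            ys.append(LABEL_TO_INT[s.label])
            gs.append(s.trial)
    X = np.stack(xs)[:, None, :, :]
    return X, np.array(ys, dtype=np.int64), np.array(gs, dtype=np.int64)


def split_train_test(y: np.ndarray, groups: np.ndarray, ratio: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Trial-grouped, class-stratified train/test split.

    All augmented children of a trial land on the same side.  Returns
    (train_indices, test_indices) into the sample axis.
    """
    if not 0 < ratio < 1:
        raise ConfigurationError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    uniq, first = np.unique(groups, return_index=True)
    trial_label = y[first]
    train_trials = []
    for lbl in np.unique(trial_label):
        trials = uniq[trial_label == lbl]
        perm = rng.permutation(trials)
        n_train = int(round(ratio * trials.size))
        train_trials.extend(perm[:n_train].tolist())
    train_set = set(train_trials)
    mask = np.array([g in train_set for g in groups])
    return np.where(mask)[0], np.where(~mask)[0]


# -------------------------------------------------------------- the model

def build_mi_cnn(seed: int = 0, dropout: float = 0.25) -> nn.Sequential:
    """Construct the reference network and verify it against the table."""
    rng = np.random.default_rng(seed)
    model = nn.Sequential([
        nn.Conv2d(1, 16, (1, 24), stride=(1, 2), padding=(0, 11), rng=rng,
                  input_grad=False),
        nn.BatchNorm2d(16),
        nn.ELU(),
        nn.Conv2d(16, 32, (2, 11), stride=(2, 1), padding=(0, 5), rng=rng),
        nn.BatchNorm2d(32),
        nn.ELU(),
        nn.AvgPool2d((2, 4)),
        nn.SpatialDropout2d(dropout, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Conv2d(32, 32, (2, 5), stride=(2, 1), padding=(0, 2), rng=rng),
        nn.BatchNorm2d(32),
        nn.ELU(),
        nn.AvgPool2d((2, 4)),
        nn.SpatialDropout2d(dropout, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Flatten(),
        nn.Linear(1024, 2, rng=rng),
    ])
    verify_architecture(model)
    return model


def model_summary(model: nn.Sequential,
                  input_shape: tuple[int, int, int] = (1, 32, 512)) -> list[dict]:
    """Per-layer output shapes and parameter counts from a dry forward."""
    x = np.zeros((1, *input_shape), dtype=np.float32)
    rows = [{"name": "input", "shape": tuple(x.shape[1:]), "params": 0}]
    for layer in model.layers:
        x = layer.forward(x, training=False)
        rows.append({
            "name": type(layer).__name__,
            "shape": tuple(x.shape[1:]),
            "params": layer.n_params,
        })
    return rows


_CHECKED_TYPES = {"Conv2d": "conv", "AvgPool2d": "pool",
                  "Flatten": "flatten", "Linear": "dense"}


def verify_architecture(model: nn.Sequential,
                        input_shape: tuple[int, int, int] = (1, 32, 512)) -> dict:
    """Check shapes and weight counts against :data:`REFERENCE_TABLE`.

    Layers are verified in order during a dry forward pass, so the
    error raised names the *first* inconsistent layer; returns the
    per-layer weight counts on success.
    """
    expected = [row for row in REFERENCE_TABLE if row[0] != "input"]
    x = np.zeros((1, *input_shape), dtype=np.float32)
    counts: dict[str, int] = {}
    counters = {"conv": 0, "pool": 0}
    pos = 0
    for layer in model.layers:
        tname = type(layer).__name__
        kind = _CHECKED_TYPES.get(tname)
        name = None
        if kind in ("conv", "pool"):
            counters[kind] += 1
            name = f"{kind}{counters[kind]}"
        elif kind:
            name = kind
        try:
            x = layer.forward(x, training=False)
        except Exception as exc:
            raise ArchitectureError(
                f"{name or tname}: forward pass failed ({exc})"
            ) from exc
        if name is None:
            continue
        if pos >= len(expected):
            raise ArchitectureError(f"unexpected extra layer {name}")
        ref_name, maps, shape, n_params = expected[pos]
        pos += 1
        if name != ref_name:
            raise ArchitectureError(
                f"layer order mismatch: found {name}, expected {ref_name}"
            )
        expected_shape = (maps, *shape) if maps is not None else shape
        if tuple(x.shape[1:]) != expected_shape:
            raise ArchitectureError(
                f"{name}: output shape {tuple(x.shape[1:])} != "
                f"expected {expected_shape}"
            )
        if n_params and layer.n_params != n_params:
            raise ArchitectureError(
                f"{name}: {layer.n_params} trainable parameters != "
                f"expected {n_params}"
            )
        counts[name] = layer.n_params
    if pos < len(expected):
        raise ArchitectureError(f"layer {expected[pos][0]} missing from the model")
    return counts


# ----------------------------------------------------------------- training

def train(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None,
          X_test: np.ndarray | None = None,
          y_test: np.ndarray | None = None) -> TrainingReport:
    """Cross-entropy training with Adam; records loss and test accuracy."""
    config = config or TrainConfig()
    if X.shape[0] == 0:
        raise ConfigurationError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    report = TrainingReport(seed=config.seed, lr=config.lr,
                            batch_size=config.batch_size,
                            n_train=int(X.shape[0]),
                            n_test=0 if X_test is None else int(X_test.shape[0]))
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(X[idx], training=True)
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at optimizer step {opt.t}"
                )
            model.backward(grad)
            opt.step()
            losses.append(loss)
        report.train_loss.append(float(np.mean(losses)))
        if X_test is not None:
            acc = evaluate(model, X_test, y_test)
            report.test_accuracy.append(acc)
            report.best_accuracy = max(report.best_accuracy, acc)
    return report


def evaluate(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
             batch_size: int = 64) -> float:
    """Fraction of samples whose argmax logit matches the label."""
    if X.shape[0] == 0:
        raise ConfigurationError("empty evaluation set")
    correct = 0
    for start in range(0, X.shape[0], batch_size):
        logits = model.forward(X[start : start + batch_size], training=False)
        correct += int((logits.argmax(axis=1) ==
                        y[start : start + batch_size]).sum())
    return correct / X.shape[0]
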