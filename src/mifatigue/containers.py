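"""In-memory containers for continuous recordings and epoched data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

LEFT = "left"
RIGHT = "right"
CLASSES = (LEFT, RIGHT)


@dataclass(frozen=True)
class Event:
    """A trial marker: sample index of imagery onset, trial id, class."""

    sample: int
    trial: int
    label: str

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ConfigurationError(f"unknown event label {self.label!r}")


@dataclass
class Recording:
    """Continuous multichannel EEG.

    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    labels
        Channel names (10-20 labels), unique.
    events
        Imagery-onset markers in acquisition order.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("channel labels must be unique")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ConfigurationError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.labels)} channel labels"
            )
        for ev in self.events:
            if not 0 <= ev.sample < self.data.shape[1]:
                raise ConfigurationError(
                    f"event for trial {ev.trial} at sample {ev.sample} "
                    f"outside recording of {self.data.shape[1]} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(f"unknown channel label {label!r}") from None

    def copy_with(self, **kwargs) -> "Recording":
        out = replace(self, **kwargs)
        return out


@dataclass
class EpochSet:
    """Trial-locked segments.

    data
        ``(n_trials, n_channels, n_times)`` array in microvolts.
    window
        Epoch extent ``(t_start, t_end)`` in seconds relative to imagery
        onset.
    baseline_window
        Interval whose per-channel mean was subtracted, seconds relative
        to imagery onset.
    trial_order
        Acquisition index of each epoch row (a permutation of 0..n-1).
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    classes: tuple[str, ...]
    window: tuple[float, float]
    baseline_window: tuple[float, float]
    trial_order: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.classes = tuple(self.classes)
        n = self.data.shape[0]
        if len(self.classes) != n:
            raise ConfigurationError("one class label per trial required")
        order = np.sort(np.asarray(self.trial_order))
        if not np.array_equal(order, np.arange(n)):
            raise ConfigurationError("trial_order must be a permutation of 0..n-1")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_times) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(f"unknown channel label {label!r}") from None

    def in_acquisition_order(self) -> "EpochSet":
        """Return a copy with trials sorted by acquisition index."""
        idx = np.argsort(self.trial_order)
        return EpochSet(
            data=self.data[idx],
            fs=self.fs,
            labels=self.labels,
            classes=tuple(self.classes[i] for i in idx),
            window=self.window,
            baseline_window=self.baseline_window,
            trial_order=np.asarray(self.trial_order)[idx],
            trial_ids=np.asarray(self.trial_ids)[idx],
        )
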