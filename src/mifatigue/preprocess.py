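"""Filtering, resampling, epoching and baseline removal.

The band-pass is a linear-phase FIR applied as a centered (zero-phase)
convolution, so oscillatory latencies are preserved.  With the default
1 Hz transition band and Hamming design the stopband is below -50 dB,
which also removes 50 Hz line interference (the passband ends at 35 Hz).

Artifact rejection is a pass-through hook here: synthetic sessions are
artifact-free.  For real data the conventional recipe recorded in
:data:`ICA_RETENTION_RULE` is ICA with an ICLabel-style classifier,
keeping components whose brain-activity probability is at least 60%.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet, Event, Recording
from .errors import ConfigurationError

#: Convention applied when cleaning real recordings externally.
ICA_RETENTION_RULE = {"method": "ICA + component classifier",
                      "keep_if_brain_probability_at_least": 0.60}


def design_bandpass(fs: float, lo: float, hi: float,
                    transition: float = 1.0) -> np.ndarray:
    """Odd-length Hamming-window FIR band-pass taps for zero-phase use."""
    if not 0 < lo < hi:
        raise ConfigurationError("need 0 < lo < hi")
    if hi >= fs / 2:
        raise ConfigurationError(
            f"high cutoff {hi} Hz must be below Nyquist ({fs / 2} Hz)"
        )
    numtaps = int(3.3 * fs / transition)
    numtaps += 1 - numtaps % 2  # odd => symmetric, integer group delay
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def bandpass(rec: Recording, lo: float = 1.0, hi: float = 35.0,
             transition: float = 1.0) -> Recording:
    """Zero-phase FIR band-pass of a continuous recording.

    The symmetric FIR is applied by centered overlap-add convolution,
    which is exactly zero-phase; edge samples within half the filter
    length of the boundaries are attenuated (sessions carry lead-in /
    lead-out padding for this reason).
    """
    taps = design_bandpass(rec.fs, lo, hi, transition)
    filtered = signal.oaconvolve(
        rec.data.astype(np.float64), taps[np.newaxis, :], mode="same", axes=1
    )
    return Recording(
        data=filtered.astype(np.float32),
        fs=rec.fs,
        labels=rec.labels,
        events=list(rec.events),
    )


def resample(rec: Recording, fs_new: float = 512.0) -> Recording:
    """Anti-aliased polyphase resampling; event indices are rescaled."""
    if fs_new > rec.fs:
        raise ConfigurationError("fs_new must not exceed the original rate")
    if fs_new == rec.fs:
        return Recording(
            data=rec.data.copy(), fs=rec.fs, labels=rec.labels,
            events=list(rec.events),
        )
    frac = Fraction(int(round(fs_new * 1000)), int(round(rec.fs * 1000)))
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data.astype(np.float64), up, down, axis=1)
    ratio = fs_new / rec.fs
    n_new = data.shape[1]
    events = [
        Event(sample=min(int(round(e.sample * ratio)), n_new - 1),
              trial=e.trial, label=e.label)
        for e in rec.events
    ]
    return Recording(data=data.astype(np.float32), fs=fs_new,
                     labels=rec.labels, events=events)


def epoch(rec: Recording, window: tuple[float, float] = (0.0, 5.0),
          baseline: tuple[float, float] = (0.0, 1.0)) -> EpochSet:
    """Cut one epoch per event and subtract the baseline mean.

    ``window`` and ``baseline`` are in seconds relative to imagery
    onset.  The per-channel mean over the baseline interval is
    subtracted from the whole epoch (an idempotent operation).
    """
    t0, t1 = window
    b0, b1 = baseline
    if not (t0 <= b0 < b1 <= t1):
        raise ConfigurationError("baseline must lie inside the epoch window")
    fs = rec.fs
    off0 = int(round(t0 * fs))
    n_times = int(round((t1 - t0) * fs))
    bl0 = int(round((b0 - t0) * fs))
    bl1 = int(round((b1 - t0) * fs))

    bad = [
        e.trial for e in rec.events
        if e.sample + off0 < 0 or e.sample + off0 + n_times > rec.n_samples
    ]
    if bad:
        raise ConfigurationError(
            f"epoch window {window} exceeds recording bounds for trials {bad}"
        )
    if not rec.events:
        raise ConfigurationError("recording has no events to epoch")

    n = len(rec.events)
    data = np.empty((n, rec.n_channels, n_times), dtype=np.float32)
    classes = []
    trial_ids = np.empty(n, dtype=int)
    for i, e in enumerate(rec.events):
        start = e.sample + off0
        seg = rec.data[:, start : start + n_times].astype(np.float64)
        seg = seg - seg[:, bl0:bl1].mean(axis=1, keepdims=True)
        data[i] = seg.astype(np.float32)
        classes.append(e.label)
        trial_ids[i] = e.trial
    return EpochSet(
        data=data, fs=fs, labels=rec.labels, classes=tuple(classes),
        window=window, baseline_window=baseline,
        trial_order=np.arange(n), trial_ids=trial_ids,
    )


def remove_baseline(epochs: EpochSet) -> EpochSet:
    """Re-apply baseline removal (idempotent on already-corrected data)."""
    t0 = epochs.window[0]
    b0, b1 = epochs.baseline_window
    bl0 = int(round((b0 - t0) * epochs.fs))
    bl1 = int(round((b1 - t0) * epochs.fs))
    data = epochs.data - epochs.data[:, :, bl0:bl1].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data, fs=epochs.fs, labels=epochs.labels, classes=epochs.classes,
        window=epochs.window, baseline_window=epochs.baseline_window,
        trial_order=epochs.trial_order.copy(), trial_ids=epochs.trial_ids.copy(),
    )


def clean_epochs(epochs: EpochSet, method: str | None = None) -> EpochSet:
    """Artifact-rejection hook.

    Synthetic sessions contain no ocular or muscular artifacts, so the
    default is a pass-through.  The hook exists so real-data users can
    plug in an ICA-based cleaner honouring :data:`ICA_RETENTION_RULE`.
    """
    if method is None:
        return epochs
    raise ConfigurationError(f"unknown artifact-rejection method {method!r}")
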