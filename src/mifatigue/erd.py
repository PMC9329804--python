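"""Event-related desynchronization: wavelet time-frequency maps,
baseline-relative quantification, and the two-sample significance test.

ERD is expressed as relative power change, ``(P - P_ref) / P_ref``,
where ``P_ref`` is the mean power of the same frequency row over the
0-1 s preparation interval of the epoch.  Negative values indicate
desynchronization; the definition is bounded below by -1 and invariant
to amplitude scaling of the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .containers import EpochSet
from .errors import ConfigurationError, DegenerateSignalError

DEFAULT_FREQS = np.arange(4.0, 36.0, 1.0)
DEFAULT_N_CYCLES = 5.0


@dataclass
class TimeFreqMap:
    """Trial-averaged wavelet power for one channel.

    ``power`` has shape ``(n_freqs, n_times)``; ``times`` are seconds on
    the epoch clock (imagery onset at 0).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline_window: tuple[float, float]
    channel: str
    normalized: bool = False


@dataclass(frozen=True)
class ErdValue:
    """Mean relative power change in one (band x time window) box."""

    channel: str
    band: tuple[float, float]
    window: tuple[float, float]
    value: float


def tf_transform(epochs: EpochSet, channel: str,
                 freqs: Sequence[float] | None = None,
                 n_cycles: float = DEFAULT_N_CYCLES,
                 cls: str | None = None) -> TimeFreqMap:
    """Complex-Morlet power, averaged over trials of one class.

    Parameters
    ----------
    channel
        10-20 label of the channel to transform.
    freqs
        Linear frequency grid in Hz; default 4-35 Hz at 1 Hz steps.
    n_cycles
        Morlet cycles (fixed across frequencies).
    cls
        Restrict to trials of this class (``"left"``/``"right"``);
        ``None`` averages all trials.
    """
    from mne.time_frequency import tfr_array_morlet

    idx = epochs.channel_index(channel)
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.min() <= 0 or freqs.max() >= epochs.fs / 2:
        raise ConfigurationError("frequencies must lie inside (0, fs/2)")
    sel = np.arange(epochs.n_trials)
    if cls is not None:
        sel = np.array([i for i, c in enumerate(epochs.classes) if c == cls])
        if sel.size == 0:
            raise ConfigurationError(f"no trials of class {cls!r}")
    data = epochs.data[sel][:, [idx], :].astype(np.float64)
    # reflection padding so wavelet power near the epoch edges (which the
    # 0-1 s baseline touches) is not biased low by zero padding
    pad = int(round(n_cycles / freqs.min() * epochs.fs))
    pad = min(pad, data.shape[-1] - 1)
    padded = np.concatenate(
        [data[..., 1 : pad + 1][..., ::-1], data, data[..., -pad - 1 : -1][..., ::-1]],
        axis=-1,
    )
    power = tfr_array_morlet(
        padded, sfreq=epochs.fs, freqs=freqs, n_cycles=n_cycles,
        output="power", verbose="error",
    )[..., pad : pad + data.shape[-1]]
    avg = power.mean(axis=0)[0]  # (n_freqs, n_times)
    return TimeFreqMap(
        power=avg, freqs=freqs, times=epochs.times,
        baseline_window=epochs.baseline_window, channel=channel,
    )


def erd_quantify(tf: TimeFreqMap, band: tuple[float, float] = (8.0, 13.0),
                 window: tuple[float, float] = (1.0, 2.5)) -> ErdValue:
    """Mean relative power change over a band x window box.

    For each frequency row the reference is the mean power over the
    baseline interval of the map; the returned value is the mean of
    ``(P - P_ref) / P_ref`` over the box.  Values below 0 indicate
    desynchronization relative to the preparation period.
    """
    rows = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    if not rows.any():
        raise ConfigurationError(f"band {band} outside the map's frequency grid")
    wcols = (tf.times >= window[0]) & (tf.times <= window[1])
    if not wcols.any():
        raise ConfigurationError(f"window {window} outside the map's time axis")
    b0, b1 = tf.baseline_window
    bcols = (tf.times >= b0) & (tf.times <= b1)
    if not bcols.any():
        raise ConfigurationError("baseline window outside the map's time axis")
    p_ref = tf.power[rows][:, bcols].mean(axis=1)
    if np.any(p_ref <= 0) or not np.all(np.isfinite(p_ref)):
        raise DegenerateSignalError("baseline power is zero or non-finite")
    rel = (tf.power[rows][:, wcols] - p_ref[:, None]) / p_ref[:, None]
    return ErdValue(channel=tf.channel, band=tuple(band),
                    window=tuple(window), value=float(rel.mean()))


def erd_ttest(group_a: Iterable, group_b: Iterable) -> tuple[float, float]:
    """Two-sample, two-tailed, pooled-variance t-test on ERD values.

    Accepts sequences of floats or :class:`ErdValue`.  Degrees of
    freedom are ``n_a + n_b - 2``.
    """
    a = np.array([v.value if isinstance(v, ErdValue) else float(v)
                  for v in group_a])
    b = np.array([v.value if isinstance(v, ErdValue) else float(v)
                  for v in group_b])
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least two values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise DegenerateSignalError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
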