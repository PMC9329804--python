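"""Mental-fatigue quantification from theta/alpha/beta band powers.

The composite fatigue index fuses the two classical band-power ratios
that rise with fatigue,

    index = w * (theta + alpha) / beta  +  (1 - w) * theta / beta

with an unweighted mean (``w = 0.5``) by default.  Fatigue-sensitive
channels are the parietal channels whose per-trial index correlates
with experiment time (trial index) above a threshold, 0.75 by default.

Band decomposition uses wavelet-packet analysis with frequency-ordered
node selection (bins of about 2 Hz), because the theta/alpha/beta edges
are not dyadic; the per-trial time course uses a Welch power-spectral-
density estimate instead (1 s segments, 50% overlap, Hann window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from .containers import EpochSet
from .errors import ConfigurationError, DegenerateSignalError
from .montage import BAND_NAMES, BANDS

_WAVELET = "db8"


@dataclass(frozen=True)
class BandPowers:
    """Energies (sums of squared samples) of the three rhythm bands."""

    theta: float
    alpha: float
    beta: float
    bands: dict = field(default_factory=lambda: dict(BANDS))

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.alpha, self.beta])


@dataclass
class FatigueSeries:
    """Per-channel, per-trial composite fatigue index (acquisition order)."""

    index: np.ndarray           # (n_channels, n_trials)
    channels: tuple[str, ...]
    trial_order: np.ndarray
    threshold: float = 0.75
    correlations: np.ndarray | None = None
    selected_channels: tuple[str, ...] | None = None

    @property
    def mean_timecourse(self) -> np.ndarray:
        """Composite index averaged over channels, per trial."""
        return self.index.mean(axis=0)

    @property
    def session_mean(self) -> float:
        """The session's average fatigue value."""
        return float(self.index.mean())


def _wp_depth(n: int, fs: float, wavelet: str = _WAVELET) -> int:
    """Decomposition depth giving ~2 Hz bins, limited by signal length."""
    want = max(1, math.ceil(math.log2((fs / 2) / 2.0)))
    return min(want, pywt.dwt_max_level(n, pywt.Wavelet(wavelet)))


def band_reconstruct(x: np.ndarray, fs: float,
                     band: tuple[float, float],
                     wavelet: str = _WAVELET) -> np.ndarray:
    """Reconstruct the part of ``x`` inside ``band`` via wavelet packets.

    Frequency-ordered packet nodes whose center frequency falls inside
    the band are kept; everything else is zeroed before reconstruction.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < fs:
        raise ConfigurationError("signal must be at least one second long")
    depth = _wp_depth(x.size, fs, wavelet)
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, maxlevel=depth)
    nodes = wp.get_level(depth, order="freq")
    bw = (fs / 2.0) / len(nodes)
    out = pywt.WaveletPacket(data=None, wavelet=wavelet, maxlevel=depth)
    kept = 0
    for i, node in enumerate(nodes):
        center = (i + 0.5) * bw
        if band[0] <= center <= band[1]:
            out[node.path] = node.data
            kept += 1
    if kept == 0:
        raise ConfigurationError(
            f"band {band} Hz too narrow for the {bw:.2f} Hz packet bins"
        )
    rec = out.reconstruct(update=False)
    return np.asarray(rec)[: x.size]


def band_decompose(x: np.ndarray, fs: float,
                   bands: dict | None = None,
                   wavelet: str = _WAVELET) -> BandPowers:
    """Theta/alpha/beta energies of one signal by wavelet-packet
    decomposition and reconstruction; power = sum of squared samples."""
    bands = dict(BANDS) if bands is None else bands
    x = np.asarray(x, dtype=np.float64)
    if x.size < fs:
        raise ConfigurationError("signal must be at least one second long")
    powers = {}
    for name in BAND_NAMES:
        rec = band_reconstruct(x, fs, bands[name], wavelet)
        powers[name] = float(np.sum(rec ** 2))
    return BandPowers(theta=powers["theta"], alpha=powers["alpha"],
                      beta=powers["beta"], bands=bands)


def fatigue_index(bp: BandPowers | tuple[float, float, float],
                  weight: float = 0.5) -> float:
    """Fused fatigue index: ``w*(theta+alpha)/beta + (1-w)*theta/beta``.

    ``weight=0.5`` is the unweighted mean of the two component ratios.
    """
    if isinstance(bp, BandPowers):
        theta, alpha, beta = bp.theta, bp.alpha, bp.beta
    else:
        theta, alpha, beta = bp
    if beta <= 0:
        raise DegenerateSignalError("beta power must be positive")
    if theta < 0 or alpha < 0:
        raise DegenerateSignalError("band powers must be non-negative")
    return weight * (theta + alpha) / beta + (1.0 - weight) * theta / beta


def _welch_band_powers(x: np.ndarray, fs: float, bands: dict) -> dict[str, float]:
    nperseg = min(int(fs), x.size)
    f, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                       window="hann")
    out = {}
    for name in BAND_NAMES:
        lo, hi = bands[name]
        m = (f >= lo) & (f <= hi)
        out[name] = float(np.trapezoid(psd[m], f[m]))
    return out


def fatigue_timecourse(epochs: EpochSet, channels,
                       bands: dict | None = None,
                       weight: float = 0.5,
                       threshold: float = 0.75) -> FatigueSeries:
    """Per-trial composite fatigue index on each requested channel.

    Band powers come from a Welch PSD per trial and channel; trials are
    returned in acquisition order so the series is a time course.
    """
    channels = tuple(channels)
    if not channels:
        raise ConfigurationError("channel set must not be empty")
    bands = dict(BANDS) if bands is None else bands
    idx = [epochs.channel_index(ch) for ch in channels]
    ordered = epochs.in_acquisition_order()
    n = ordered.n_trials
    index = np.empty((len(channels), n))
    for ci, di in enumerate(idx):
        for t in range(n):
            bp = _welch_band_powers(ordered.data[t, di], ordered.fs, bands)
            index[ci, t] = fatigue_index(
                (bp["theta"], bp["alpha"], bp["beta"]), weight
            )
    return FatigueSeries(index=index, channels=channels,
                         trial_order=np.arange(n), threshold=threshold)


def select_sensitive_channels(series: FatigueSeries,
                              threshold: float | None = None) -> list[str]:
    """Channels whose index rises with experiment time.

    Pearson correlation of the per-trial index against trial order is
    computed per channel; channels with ``r > threshold`` are selected
    (one-sided: fatigue is expected to rise).  A constant series has no
    defined correlation and is treated as ``r = 0``.
    """
    if threshold is None:
        threshold = series.threshold
    n = series.index.shape[1]
    if n < 3:
        raise ConfigurationError("need at least three trials per channel")
    t = np.arange(n, dtype=float)
    rs = np.zeros(len(series.channels))
    for ci in range(len(series.channels)):
        y = series.index[ci]
        if np.std(y) == 0:
            rs[ci] = 0.0
        else:
            rs[ci] = stats.pearsonr(y, t).statistic
    selected = [ch for ch, r in zip(series.channels, rs) if r > threshold]
    series.correlations = rs
    series.selected_channels = tuple(selected)
    series.threshold = threshold
    return selected
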