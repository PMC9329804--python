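"""Phase-locking value between parietal and frontal channels.

The instantaneous phase is estimated by narrowband FIR filtering
followed by the analytic signal (Hilbert transform); 10% of the samples
at each edge are discarded to avoid filter and Hilbert edge artifacts.
For two phase series the PLV is

    PLV = | < exp(i (phi_x(t) - phi_y(t))) >_t |
        = sqrt( <cos phi_xy>^2 + <sin phi_xy>^2 ) ,

which is 1 for perfectly synchronized phases (including a constant
offset) and near ``sqrt(pi) / (2 sqrt(n))`` for independent phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import EpochSet
from .errors import ConfigurationError, DegenerateSignalError
from .montage import BANDS, FRONTAL_SET

DEFAULT_BAND = BANDS["alpha"]


@dataclass
class PhaseSeries:
    """Instantaneous phase in radians after edge trimming."""

    phi: np.ndarray
    band: tuple[float, float]
    fs: float
    channel: str | None = None

    @property
    def n_samples(self) -> int:
        return self.phi.size


@dataclass
class PLVResult:
    """Trial-averaged PLV per (parietal, frontal) pair."""

    pairs: dict
    parietal: str
    band: tuple[float, float]
    n_samples: int

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.pairs.values())))


def instantaneous_phase(x: np.ndarray, fs: float,
                        band: tuple[float, float] = DEFAULT_BAND,
                        edge_fraction: float = 0.1,
                        channel: str | None = None) -> PhaseSeries:
    """Narrowband-filter ``x`` and return the analytic-signal phase.

    Raises :class:`DegenerateSignalError` for an (all-zero) signal whose
    phase is undefined.  Requires at least 2 s of signal.
    """
    x = np.asarray(x, dtype=np.float64)
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ConfigurationError(f"band {band} must lie inside (0, Nyquist)")
    if x.size < 2 * fs:
        raise ConfigurationError("need at least 2 s of signal for phase")
    if not np.any(x):
        raise DegenerateSignalError("phase of an all-zero signal is undefined")
    transition = max((hi - lo) / 2.0, 1.0)
    numtaps = int(3.3 * fs / transition)
    numtaps = min(numtaps, 2 * (x.size // 3) - 1)
    numtaps += 1 - numtaps % 2
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    y = sps.oaconvolve(x, taps, mode="same")
    phi = np.angle(sps.hilbert(y))
    k = int(edge_fraction * phi.size)
    if k:
        phi = phi[k:-k]
    return PhaseSeries(phi=phi, band=(lo, hi), fs=fs, channel=channel)


def plv(phi_x: PhaseSeries | np.ndarray, phi_y: PhaseSeries | np.ndarray) -> float:
    """Phase-locking value of two equally long phase series."""
    px = phi_x.phi if isinstance(phi_x, PhaseSeries) else np.asarray(phi_x)
    py = phi_y.phi if isinstance(phi_y, PhaseSeries) else np.asarray(phi_y)
    if px.size != py.size:
        raise ConfigurationError(
            f"phase series lengths differ: {px.size} vs {py.size}"
        )
    if px.size == 0:
        raise ConfigurationError("empty phase series")
    d = px - py
    return float(np.hypot(np.cos(d).mean(), np.sin(d).mean()))


def plv_panel(epochs: EpochSet, parietal: str,
              frontal_set=FRONTAL_SET,
              band: tuple[float, float] = DEFAULT_BAND) -> PLVResult:
    """Trial-averaged PLV between one parietal and several frontal channels.

    The PLV is computed per trial (avoiding phase jumps at trial
    boundaries) and averaged over trials for each pair.
    """
    frontal_set = tuple(frontal_set)
    pi = epochs.channel_index(parietal)
    fi = [epochs.channel_index(ch) for ch in frontal_set]
    values = {ch: [] for ch in frontal_set}
    n_samples = 0
    for t in range(epochs.n_trials):
        pp = instantaneous_phase(epochs.data[t, pi], epochs.fs, band,
                                 channel=parietal)
        n_samples = pp.n_samples
        for ch, di in zip(frontal_set, fi):
            fp = instantaneous_phase(epochs.data[t, di], epochs.fs, band,
                                     channel=ch)
            values[ch].append(plv(pp, fp))
    pairs = {(parietal, ch): float(np.mean(v)) for ch, v in values.items()}
    return PLVResult(pairs=pairs, parietal=parietal, band=tuple(band),
                     n_samples=n_samples)
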