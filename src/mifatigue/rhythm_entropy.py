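"""Rhythm entropy: Shannon entropy of the theta/alpha/beta energy shares.

For each trial and channel the three rhythm-band signals are extracted
(sharing the wavelet-packet band decomposition of the fatigue module),
their energies are

    Power_j = sum_i S_j(i)^2 ,

the shares are ``P_j = Power_j / sum_j Power_j``, and the rhythm
entropy in bits is

    En = - sum_j P_j log2 P_j ,

bounded in ``[0, log2 3]`` for three bands.  Low entropy means the
spectrum is concentrated in one rhythm (ordered activity); a fatigued
brain whose activity collapses toward a single rhythm shows a drop in
En, whereas a flattening spectrum raises it.

The awake/fatigue contrast follows the session protocol: the first 20
trials (acquisition order) are the awake state, the last 20 the
fatigued state, averaged over the six frontal channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .errors import ConfigurationError, DegenerateSignalError
from .fatigue import band_decompose
from .montage import BANDS, FRONTAL_SET


@dataclass
class EntropyReport:
    """Per-trial rhythm entropy (bits) per channel, plus state means."""

    en: np.ndarray                  # (n_channels, n_trials) acquisition order
    channels: tuple[str, ...]
    awake_mean: float
    fatigue_mean: float
    n_state_trials: int


def band_energy(x: np.ndarray) -> float:
    """Energy of a band-reconstructed signal: the sum of squared samples."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ConfigurationError("empty signal has no energy")
    return float(np.sum(x ** 2))


def normalize_powers(powers) -> np.ndarray:
    """Normalize band energies to shares summing to one."""
    p = np.asarray(powers, dtype=np.float64)
    if np.any(p < 0):
        raise DegenerateSignalError("band energies must be non-negative")
    total = p.sum()
    if total <= 0:
        raise DegenerateSignalError("all band energies are zero")
    return p / total


def rhythm_entropy(p) -> float:
    """Shannon entropy in bits of a share vector (0*log0 := 0)."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise DegenerateSignalError("shares must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise DegenerateSignalError("shares must sum to one")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def trial_entropy(x: np.ndarray, fs: float, bands: dict | None = None) -> float:
    """Rhythm entropy of one trial of one channel."""
    bands = dict(BANDS) if bands is None else bands
    bp = band_decompose(x, fs, bands)
    return rhythm_entropy(normalize_powers(bp.as_array()))


def awake_fatigue_summary(epochs: EpochSet,
                          channels=FRONTAL_SET,
                          n_state_trials: int = 20,
                          bands: dict | None = None) -> EntropyReport:
    """Frontal rhythm entropy in the awake vs fatigued state.

    The first ``n_state_trials`` trials (acquisition order) define the
    awake state, the last ``n_state_trials`` the fatigued state; the
    report averages En across the given channels within each state.
    """
    channels = tuple(channels)
    idx = [epochs.channel_index(ch) for ch in channels]
    ordered = epochs.in_acquisition_order()
    n = ordered.n_trials
    if n < 2 * n_state_trials:
        raise ConfigurationError(
            f"need at least {2 * n_state_trials} trials, got {n}"
        )
    bands = dict(BANDS) if bands is None else bands
    en = np.empty((len(channels), n))
    for ci, di in enumerate(idx):
        for t in range(n):
            en[ci, t] = trial_entropy(ordered.data[t, di], ordered.fs, bands)
    return EntropyReport(
        en=en, channels=channels,
        awake_mean=float(en[:, :n_state_trials].mean()),
        fatigue_mean=float(en[:, -n_state_trials:].mean()),
        n_state_trials=n_state_trials,
    )
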