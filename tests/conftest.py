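import numpy as np
import pytest
from scipy import signal

import mifatigue as mf


def bandpower_oracle(x: np.ndarray, fs: float, band: tuple[float, float],
                     numtaps: int = 1025) -> np.ndarray:
    """Brute-force band power: FIR band-pass then mean of squares.

    Independent of the package's wavelet/Welch estimators; used to
    verify planted effects directly on generated arrays.
    """
    taps = signal.firwin(numtaps, list(band), pass_zero=False, fs=fs)
    y = signal.oaconvolve(np.asarray(x, dtype=float), taps, mode="same")
    return y


@pytest.fixture(scope="session")
def small_recording() -> mf.Recording:
    """1 run x 8 trials, six channels, planted ERD only."""
    cfg = mf.SessionConfig(
        n_runs=1, trials_per_run=8,
        channels=("C3", "C4", "Cz", "F3", "P6", "P2"),
        erd_attenuation=0.5, noise_sd=0.5,
        fatigue_drift={}, drift_channels=(), coupled_pairs=(),
        seed=7,
    )
    return mf.generate_session(cfg)


@pytest.fixture(scope="session")
def small_epochs(small_recording) -> mf.EpochSet:
    filt = mf.bandpass(small_recording)
    return mf.epoch(mf.resample(filt, 512.0))


def make_epochset(trials: np.ndarray, fs: float, labels, classes=None,
                  window=(0.0, 5.0), baseline=(0.0, 1.0)) -> mf.EpochSet:
    """Build an EpochSet directly from an array (n, ch, t)."""
    n = trials.shape[0]
    if classes is None:
        classes = tuple(mf.LEFT if i % 2 else mf.RIGHT for i in range(n))
    return mf.EpochSet(
        data=np.asarray(trials, dtype=np.float32), fs=fs, labels=tuple(labels),
        classes=tuple(classes), window=window, baseline_window=baseline,
        trial_order=np.arange(n), trial_ids=np.arange(n),
    )
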