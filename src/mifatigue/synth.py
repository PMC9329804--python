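"""Synthetic motor-imagery EEG sessions.

The generator emulates a cued left/right-hand motor-imagery experiment:
runs of trials, each trial a 3 s blank screen, a 3 s movement-video cue
and 5 s of imagery, recorded from a 10-20 cap at 1,024 Hz.

Signal model, per channel:

    x(t) = pink(t) + sum_b  A_b * g_b(t) * o_b(t) + w(t)

where ``pink`` is 1/f background activity, ``o_b`` are unit-variance
band-limited Gaussian oscillators for the theta/alpha/beta rhythms,
``g_b`` is a per-channel amplitude envelope encoding the planted
effects, and ``w`` is white sensor noise.  Three effects are planted:

* **ERD** — during the imagery period (by default from 1 s after onset,
  leaving a 0-1 s preparation interval as reference) the alpha and beta
  envelopes of the motor channel contralateral to the imagined hand are
  scaled by ``sqrt(1 - erd_attenuation)``, so relative band power drops
  by exactly ``erd_attenuation``.
* **Fatigue drift** — on designated channels the band power of trial
  ``t`` is scaled by ``1 + slope_b * t``, a linear drift over the
  session.
* **Phase coupling** — for each (parietal, frontal, strength) pair the
  frontal alpha oscillator is ``sqrt(s)`` times the parietal one plus
  ``sqrt(1-s)`` of an independent component, which makes the
  phase-locking value between the pair a monotone function of ``s``.

Every statistic the analysis stages estimate therefore has a known
planted value that brute-force estimators can recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import CLASSES, LEFT, RIGHT, Event, Recording
from .errors import ConfigurationError
from .montage import (BANDS, CHANNEL_ORDER_32, LEFT_HAND_ERD_REGION,
                      MONTAGE_64, PARIETAL_CANDIDATES, RIGHT_HAND_ERD_REGION)


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one synthetic session.

    Amplitudes are RMS microvolts; drift slopes are relative band-power
    change per trial; ``erd_attenuation`` is the fraction of alpha/beta
    power removed on the contralateral motor channel during imagery.
    """

    n_runs: int = 4
    trials_per_run: int = 40
    fs: float = 1024.0
    channels: tuple[str, ...] = MONTAGE_64
    blank_s: float = 3.0
    cue_s: float = 3.0
    imagery_s: float = 5.0
    rest_every: int = 10
    rest_s: float = 0.0
    inter_run_s: float = 0.0
    erd_attenuation: float = 0.5
    erd_window: tuple[float, float] = (1.0, 5.0)
    erd_channels: dict = field(
        default_factory=lambda: {LEFT: "C4", RIGHT: "C3"}
    )
    fatigue_drift: dict = field(
        default_factory=lambda: {"theta": 0.008, "alpha": 0.003, "beta": -0.002}
    )
    drift_channels: tuple[str, ...] = PARIETAL_CANDIDATES
    coupled_pairs: tuple[tuple[str, str, float], ...] = (("P6", "F3", 0.6),)
    band_amplitudes: dict = field(
        default_factory=lambda: {"theta": 3.0, "alpha": 6.0, "beta": 2.0}
    )
    pink_amplitude: float = 5.0
    noise_sd: float = 1.0
    lead_in_s: float = 2.0
    lead_out_s: float = 2.0
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def trial_s(self) -> float:
        return self.blank_s + self.cue_s + self.imagery_s

    def validate(self) -> None:
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise ConfigurationError("need at least one run and one trial")
        if self.trials_per_run % 2:
            raise ConfigurationError(
                "trials_per_run must be even for left/right class balance"
            )
        for name in ("blank_s", "cue_s", "imagery_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.erd_attenuation < 1.0:
            raise ConfigurationError("erd_attenuation must lie in [0, 1)")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channel list contains duplicates")
        chset = set(self.channels)
        for cls, chs in self.erd_channels.items():
            if cls not in CLASSES:
                raise ConfigurationError(f"unknown class {cls!r} in erd_channels")
            for ch in ([chs] if isinstance(chs, str) else chs):
                if self.erd_attenuation > 0 and ch not in chset:
                    raise ConfigurationError(
                        f"ERD channel {ch!r} not in channel set"
                    )
        groups = [
            {chs} if isinstance(chs, str) else set(chs)
            for chs in self.erd_channels.values()
        ]
        if len(groups) == 2 and groups[0] & groups[1]:
            raise ConfigurationError(
                "ERD channel sets of the two classes must be disjoint"
            )
        for p, f, s in self.coupled_pairs:
            if p not in chset:
                raise ConfigurationError(f"coupled-pair channel {p!r} not in channel set")
            if f not in chset:
                raise ConfigurationError(f"coupled-pair channel {f!r} not in channel set")
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError("coupling strength must lie in [0, 1]")
        sources = {p for p, _, _ in self.coupled_pairs}
        targets = [f for _, f, _ in self.coupled_pairs]
        if len(set(targets)) != len(targets):
            raise ConfigurationError("each frontal channel may appear in one pair only")
        if sources & set(targets):
            raise ConfigurationError(
                "a channel cannot be both source and target of coupling"
            )
        for ch in self.drift_channels:
            if ch not in chset:
                raise ConfigurationError(f"drift channel {ch!r} not in channel set")
        if not (self.erd_window[0] >= 0 and self.erd_window[1] <= self.imagery_s):
            raise ConfigurationError("erd_window must lie inside the imagery period")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        d["drift_channels"] = list(self.drift_channels)
        d["coupled_pairs"] = [list(p) for p in self.coupled_pairs]
        d["erd_window"] = list(self.erd_window)
        return d


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz (FFT synthesis)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(mask.sum())
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-power background, flat below 1 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _schedule(cfg: SessionConfig) -> tuple[int, list[tuple[int, int]]]:
    """Total sample count and (trial_start, imagery_onset) samples per trial."""
    fs = cfg.fs
    cursor = int(round(cfg.lead_in_s * fs))
    trial_len = int(round(cfg.trial_s * fs))
    imagery_off = int(round((cfg.blank_s + cfg.cue_s) * fs))
    rest_len = int(round(cfg.rest_s * fs))
    run_gap = int(round(cfg.inter_run_s * fs))
    marks: list[tuple[int, int]] = []
    for run in range(cfg.n_runs):
        for t in range(cfg.trials_per_run):
            marks.append((cursor, cursor + imagery_off))
            cursor += trial_len
            if cfg.rest_every and (t + 1) % cfg.rest_every == 0:
                cursor += rest_len
        if run < cfg.n_runs - 1:
            cursor += run_gap
    total = cursor + int(round(cfg.lead_out_s * fs))
    return total, marks


def _class_sequence(cfg: SessionConfig, rng: np.random.Generator) -> list[str]:
    seq: list[str] = []
    half = cfg.trials_per_run // 2
    for _ in range(cfg.n_runs):
        run = np.array([LEFT] * half + [RIGHT] * half)
        rng.shuffle(run)
        seq.extend(run.tolist())
    return seq


def generate_session(cfg: SessionConfig) -> Recording:
    """Simulate one session and return the continuous Recording.

    Deterministic for a fixed ``cfg.seed``.  Events mark every imagery
    onset; classes are balanced within each run.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n_total, marks = _schedule(cfg)
    classes = _class_sequence(cfg, rng)
    ramp = int(round(0.1 * fs))

    drift_set = set(cfg.drift_channels)
    pair_by_target = {f: (p, s) for p, f, s in cfg.coupled_pairs}
    sources = sorted({p for p, _, _ in cfg.coupled_pairs})

    # Per-band amplitude envelopes shared by all channels of a group.
    # Power envelopes: drift multiplies trial spans; ERD multiplies the
    # imagery window of the contralateral motor channel.
    trial_len = int(round(cfg.trial_s * fs))

    def drift_envelope(band: str) -> np.ndarray:
        slope = float(cfg.fatigue_drift.get(band, 0.0))
        env = np.ones(n_total)
        if slope == 0.0:
            return env
        for t, (start, _) in enumerate(marks):
            env[start:start + trial_len] = math.sqrt(max(1.0 + slope * t, 0.0))
        return env

    drift_envs = {b: drift_envelope(b) for b in BANDS} if drift_set else None

    def erd_envelope() -> dict[str, np.ndarray]:
        """Amplitude envelope per ERD channel (applied to alpha and beta)."""
        factor = math.sqrt(1.0 - cfg.erd_attenuation)
        out: dict[str, np.ndarray] = {}
        if cfg.erd_attenuation == 0.0:
            return out
        w0 = int(round(cfg.erd_window[0] * fs))
        w1 = int(round(cfg.erd_window[1] * fs))
        gate = np.ones(w1 - w0)
        r = min(ramp, (w1 - w0) // 2)
        if r > 1:
            edge = 0.5 - 0.5 * np.cos(np.linspace(0.0, np.pi, r))
            gate[:r] = edge
            gate[-r:] = edge[::-1]
        for cls, chs in cfg.erd_channels.items():
            env = np.ones(n_total)
            for (_, onset), label in zip(marks, classes):
                if label != cls:
                    continue
                a, b = onset + w0, onset + w1
                env[a:b] -= (1.0 - factor) * gate[: b - a]
            for ch in ([chs] if isinstance(chs, str) else chs):
                out[ch] = env
        return out

    erd_envs = erd_envelope()

    # Alpha oscillators of coupling sources are generated first, in sorted
    # order, so channel iteration order does not change their realization.
    source_alpha = {
        p: _narrowband_noise(rng, n_total, fs, *BANDS["alpha"]) for p in sources
    }

    data = np.empty((len(cfg.channels), n_total), dtype=np.float32)
    for ci, ch in enumerate(cfg.channels):
        x = cfg.pink_amplitude * _pink_noise(rng, n_total, fs)
        for band, (lo, hi) in BANDS.items():
            if band == "alpha" and ch in source_alpha:
                osc = source_alpha[ch]
            elif band == "alpha" and ch in pair_by_target:
                src, s = pair_by_target[ch]
                indep = _narrowband_noise(rng, n_total, fs, lo, hi)
                osc = math.sqrt(s) * source_alpha[src] + math.sqrt(1.0 - s) * indep
            else:
                osc = _narrowband_noise(rng, n_total, fs, lo, hi)
            amp = float(cfg.band_amplitudes.get(band, 0.0))
            if amp == 0.0:
                continue
            env = None
            if ch in drift_set and drift_envs is not None:
                env = drift_envs[band].copy()
            if band in ("alpha", "beta") and ch in erd_envs:
                env = erd_envs[ch].copy() if env is None else env * erd_envs[ch]
            x += amp * (osc if env is None else env * osc)
        if cfg.noise_sd > 0:
            x += rng.normal(0.0, cfg.noise_sd, n_total)
        data[ci] = x.astype(np.float32)

    events = [
        Event(sample=onset, trial=t, label=classes[t])
        for t, (_, onset) in enumerate(marks)
    ]
    return Recording(data=data, fs=fs, labels=tuple(cfg.channels), events=events)


def strongly_separable_config(n_trials: int = 24, seed: int = 0,
                              erd_attenuation: float = 0.9,
                              noise_sd: float = 0.2) -> SessionConfig:
    """Session preset with a maximally class-discriminative ERD pattern.

    Desynchronization covers the whole contralateral sensorimotor
    region (not just C3/C4), the attenuation is deep, and sensor noise
    is low, emulating a subject with textbook lateralized rhythm
    suppression.  Used to probe the classifier's ceiling.
    """
    return SessionConfig(
        n_runs=1, trials_per_run=n_trials, channels=CHANNEL_ORDER_32,
        erd_attenuation=erd_attenuation, noise_sd=noise_sd,
        erd_channels={RIGHT: RIGHT_HAND_ERD_REGION,
                      LEFT: LEFT_HAND_ERD_REGION},
        fatigue_drift={}, drift_channels=(), coupled_pairs=(),
        seed=seed,
    )
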