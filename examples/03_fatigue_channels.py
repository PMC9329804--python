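"""Fatigue index time course and fatigue-sensitive channel selection.

Plants a linear theta-up/beta-down band-power drift on parietal
channels P2 and P4 and shows that the fused (theta+alpha)/beta &
theta/beta index selects exactly those channels at the 0.75
correlation threshold.
"""

import numpy as np

import mifatigue as mf

cfg = mf.SessionConfig(
    n_runs=2, trials_per_run=40,
    channels=mf.PARIETAL_CANDIDATES + ("C3", "C4"),
    fatigue_drift={"theta": 0.06, "alpha": 0.04, "beta": -0.01},
    drift_channels=("P2", "P4"), coupled_pairs=(), seed=11,
)
rec = mf.generate_session(cfg)
epochs = mf.epoch(mf.resample(mf.bandpass(rec), 512.0))

series = mf.fatigue_timecourse(epochs, mf.PARIETAL_CANDIDATES)
selected = mf.select_sensitive_channels(series)  # threshold 0.75

print("correlation of fatigue index with trial order:")
for ch, r in zip(series.channels, series.correlations):
    mark = " <- sensitive" if ch in selected else ""
    print(f"  {ch}: r = {r:+.3f}{mark}")
print(f"selected channels: {selected} (drift planted on P2, P4)")
print(f"session mean fatigue value: {series.session_mean:.2f}")
tc = series.mean_timecourse
print(f"index over trials: first 10 mean {tc[:10].mean():.2f}, "
      f"last 10 mean {tc[-10:].mean():.2f} (rising = fatiguing)")
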