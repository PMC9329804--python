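"""Generator contracts: determinism, scheduling, planted effects."""

import numpy as np
import pytest

import mifatigue as mf
from conftest import bandpower_oracle


def _cfg(**kw):
    base = dict(n_runs=1, trials_per_run=4, channels=("C3", "C4", "Cz"),
                fatigue_drift={}, drift_channels=(), coupled_pairs=(), seed=7)
    base.update(kw)
    return mf.SessionConfig(**base)


def test_same_seed_bit_identical():
    a = mf.generate_session(_cfg())
    b = mf.generate_session(_cfg())
    assert np.array_equal(a.data, b.data)
    assert a.events == b.events


def test_different_seed_different_noise():
    a = mf.generate_session(_cfg(seed=1))
    b = mf.generate_session(_cfg(seed=2))
    assert not np.array_equal(a.data, b.data)


def test_event_count_and_class_balance():
    rec = mf.generate_session(_cfg(n_runs=2, trials_per_run=6))
    assert len(rec.events) == 12
    labels = [e.label for e in rec.events]
    assert labels.count(mf.LEFT) == labels.count(mf.RIGHT) == 6
    # per-run balance as configured
    assert labels[:6].count(mf.LEFT) == 3


def test_events_at_imagery_onset():
    cfg = _cfg()
    rec = mf.generate_session(cfg)
    first = int(round((cfg.lead_in_s + cfg.blank_s + cfg.cue_s) * cfg.fs))
    assert rec.events[0].sample == first


@pytest.mark.parametrize("bad", [
    dict(erd_attenuation=1.0),
    dict(erd_attenuation=-0.1),
    dict(coupled_pairs=(("P6", "F3", 0.5),)),      # channels absent
    dict(coupled_pairs=(("C3", "C4", 1.5),), channels=("C3", "C4")),
    dict(drift_channels=("P9",)),
    dict(trials_per_run=5),
])
def test_invalid_configuration_rejected(bad):
    with pytest.raises(mf.ConfigurationError):
        mf.generate_session(_cfg(**bad))


def test_planted_erd_alpha_ratio():
    """Contralateral alpha power during imagery drops by ~erd_attenuation,
    measured with a brute-force band-pass + mean-square oracle."""
    cfg = _cfg(trials_per_run=16, erd_attenuation=0.5, noise_sd=0.1)
    rec = mf.generate_session(cfg)
    fs = int(cfg.fs)
    alpha = bandpower_oracle(rec.data[0], cfg.fs, (8, 13))  # C3
    base_p, img_p = [], []
    for ev in rec.events:
        if ev.label != mf.RIGHT:
            continue
        base_p.append((alpha[ev.sample : ev.sample + fs] ** 2).mean())
        seg = alpha[ev.sample + int(1.2 * fs) : ev.sample + int(4.8 * fs)]
        img_p.append((seg ** 2).mean())
    ratio = np.mean(img_p) / np.mean(base_p)
    assert ratio == pytest.approx(0.5, abs=0.1)


def test_planted_drift_slope_recovered():
    """Theta power rises linearly with trial index on drift channels."""
    slope = 0.06
    cfg = _cfg(trials_per_run=24, channels=("P2", "Cz"),
               erd_attenuation=0.0,
               fatigue_drift={"theta": slope}, drift_channels=("P2",))
    rec = mf.generate_session(cfg)
    fs = int(cfg.fs)
    theta = bandpower_oracle(rec.data[0], cfg.fs, (4, 7))
    powers = [
        (theta[e.sample : e.sample + 5 * fs] ** 2).mean() for e in rec.events
    ]
    t = np.arange(len(powers))
    b, a = np.polyfit(t, powers, 1)
    assert b / a == pytest.approx(slope, rel=0.5)
    # the non-drift channel stays flat in comparison
    theta_cz = bandpower_oracle(rec.data[1], cfg.fs, (4, 7))
    p_cz = [(theta_cz[e.sample : e.sample + 5 * fs] ** 2).mean()
            for e in rec.events]
    b2, a2 = np.polyfit(t, p_cz, 1)
    assert abs(b2 / a2) < slope / 3


def test_coupling_raises_phase_locking():
    def mean_plv(strength):
        cfg = _cfg(trials_per_run=6, channels=("P6", "F3", "Cz"),
                   erd_attenuation=0.0,
                   coupled_pairs=(("P6", "F3", strength),))
        rec = mf.generate_session(cfg)
        vals = []
        for ev in rec.events:
            sl = slice(ev.sample, ev.sample + int(5 * cfg.fs))
            px = mf.instantaneous_phase(rec.data[0, sl], cfg.fs)
            py = mf.instantaneous_phase(rec.data[1, sl], cfg.fs)
            vals.append(mf.plv(px, py))
        return np.mean(vals)

    assert mean_plv(0.9) > mean_plv(0.0) + 0.2
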