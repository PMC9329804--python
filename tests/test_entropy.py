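"""Rhythm-entropy equations and the awake/fatigue contrast."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mifatigue as mf
from conftest import make_epochset


def test_band_energy_examples():
    assert mf.band_energy([1.0, 1.0, 1.0, 1.0]) == 4.0
    assert mf.band_energy(np.zeros(16)) == 0.0
    n = 512
    x = np.sin(2 * np.pi * 8 * np.arange(n) / 512.0)  # integer periods
    assert mf.band_energy(x) == pytest.approx(n / 2, rel=1e-6)


def test_band_energy_empty_rejected():
    with pytest.raises(mf.ConfigurationError):
        mf.band_energy([])


def test_normalize_powers_examples():
    np.testing.assert_allclose(mf.normalize_powers([2, 1, 1]), [0.5, 0.25, 0.25])
    np.testing.assert_allclose(mf.normalize_powers([5, 0, 0]), [1, 0, 0])
    with pytest.raises(mf.DegenerateSignalError):
        mf.normalize_powers([0.0, 0.0, 0.0])


def test_entropy_analytic_values():
    assert mf.rhythm_entropy([1 / 3] * 3) == pytest.approx(np.log2(3), abs=1e-12)
    assert mf.rhythm_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5, abs=1e-12)
    assert mf.rhythm_entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0, abs=1e-12)


def test_entropy_invalid_inputs_rejected():
    with pytest.raises(mf.DegenerateSignalError):
        mf.rhythm_entropy([0.5, 0.6, 0.2])
    with pytest.raises(mf.DegenerateSignalError):
        mf.rhythm_entropy([-0.1, 0.6, 0.5])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=3, max_size=3))
def test_entropy_bounded_on_normalized_shares(raw):
    p = mf.normalize_powers(raw)
    en = mf.rhythm_entropy(p)
    assert -1e-9 <= en <= np.log2(3) + 1e-9


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(min_value=1e-3, max_value=1.0), min_size=3, max_size=3),
       st.lists(st.floats(min_value=1e-3, max_value=1.0), min_size=3, max_size=3),
       st.floats(min_value=0.0, max_value=1.0))
def test_entropy_concave_under_mixing(a, b, lam):
    """Mixing two share profiles never drops entropy below the mixture of
    the endpoint entropies (concavity of Shannon entropy)."""
    pa, pb = mf.normalize_powers(a), mf.normalize_powers(b)
    mixed = lam * pa + (1 - lam) * pb
    lower = lam * mf.rhythm_entropy(pa) + (1 - lam) * mf.rhythm_entropy(pb)
    assert mf.rhythm_entropy(mixed) >= lower - 1e-9


def test_trial_entropy_amplitude_invariant():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(1024)
    fs = 512.0
    assert mf.trial_entropy(x, fs) == pytest.approx(
        mf.trial_entropy(10.0 * x, fs), rel=1e-9
    )


def _mixture_epochs(amp_schedule, fs=256.0, dur=2.0, seed=0):
    """40 single-channel trials whose (theta, alpha, beta) amplitudes
    follow amp_schedule(trial_index)."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(dur * fs)) / fs
    trials = []
    for i in range(40):
        a_t, a_a, a_b = amp_schedule(i)
        x = (a_t * np.sin(2 * np.pi * 5 * t + rng.uniform(0, 2 * np.pi))
             + a_a * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
             + a_b * np.sin(2 * np.pi * 20 * t + rng.uniform(0, 2 * np.pi))
             + 0.05 * rng.standard_normal(t.size))
        trials.append(x[None, :])
    return make_epochset(np.stack(trials), fs, ("F3",),
                         window=(0.0, dur), baseline=(0.0, 1.0))


def test_entropy_falls_when_late_trials_concentrate():
    """Power concentrating into theta late in the session lowers En."""
    ep = _mixture_epochs(lambda i: (1.0 + 0.1 * i, 1.0, 1.0))
    rep = mf.awake_fatigue_summary(ep, channels=("F3",))
    assert rep.fatigue_mean < rep.awake_mean


def test_entropy_rises_when_late_trials_flatten():
    """An alpha-dominant spectrum flattening over trials raises En."""
    ep = _mixture_epochs(lambda i: (0.3 + 0.05 * i, 3.0, 0.3 + 0.05 * i))
    rep = mf.awake_fatigue_summary(ep, channels=("F3",))
    assert rep.fatigue_mean > rep.awake_mean


def test_summary_needs_forty_trials(small_epochs):
    with pytest.raises(mf.ConfigurationError):
        mf.awake_fatigue_summary(small_epochs, channels=("F3",))
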