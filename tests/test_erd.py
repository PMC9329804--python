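"""Time-frequency analysis and ERD quantification."""

import numpy as np
import pytest

import mifatigue as mf
from conftest import make_epochset


def sine_epochs(freq=10.0, fs=512.0, n=2, amp=1.0):
    t = np.arange(int(5 * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t)
    return make_epochset(np.tile(sig, (n, 1, 1)), fs, ("C3",))


def test_oscillator_localized_in_frequency():
    tf = mf.tf_transform(sine_epochs(10.0), "C3")
    row_power = tf.power[:, 256:-256].mean(axis=1)
    assert abs(tf.freqs[int(np.argmax(row_power))] - 10.0) <= 1.0


def test_power_is_quadratic_in_amplitude():
    tf1 = mf.tf_transform(sine_epochs(10.0, amp=1.0), "C3")
    tf2 = mf.tf_transform(sine_epochs(10.0, amp=2.0), "C3")
    i = int(np.argmax(tf1.power[:, 1280]))
    ratio = tf2.power[i, 1280] / tf1.power[i, 1280]
    assert ratio == pytest.approx(4.0, rel=0.05)


def test_unknown_channel_rejected():
    with pytest.raises(mf.ConfigurationError):
        mf.tf_transform(sine_epochs(), "C9")


def _flat_map(level_window=0.5):
    freqs = np.arange(8.0, 14.0)
    times = np.arange(0, 2560) / 512.0
    power = np.ones((freqs.size, times.size))
    power[:, times > 1.0] = level_window
    return mf.TimeFreqMap(power=power, freqs=freqs, times=times,
                          baseline_window=(0.0, 1.0), channel="C3")


def test_erd_zero_when_power_equals_baseline():
    val = mf.erd_quantify(_flat_map(1.0), (8, 13), (1.1, 2.5))
    assert val.value == pytest.approx(0.0, abs=1e-12)


def test_erd_matches_relative_change_definition():
    val = mf.erd_quantify(_flat_map(0.5), (8, 13), (1.1, 2.5))
    assert val.value == pytest.approx(-0.5, abs=1e-12)


def test_zero_baseline_power_rejected():
    tf = _flat_map(0.5)
    tf.power[:, tf.times <= 1.0] = 0.0
    with pytest.raises(mf.DegenerateSignalError):
        mf.erd_quantify(tf, (8, 13), (1.0, 2.5))


def test_erd_invariant_to_amplitude_scaling(small_epochs):
    tf1 = mf.tf_transform(small_epochs, "C3", cls=mf.RIGHT)
    scaled = make_epochset(small_epochs.data * 3.0, small_epochs.fs,
                           small_epochs.labels, small_epochs.classes)
    tf2 = mf.tf_transform(scaled, "C3", cls=mf.RIGHT)
    v1 = mf.erd_quantify(tf1).value
    v2 = mf.erd_quantify(tf2).value
    assert v1 == pytest.approx(v2, abs=1e-6)


# Published worked example: quantified ERD values for channels C3/C4 in
# the preparation (0-1 s) vs execution (1-2.5 s) windows, three runs of
# one subject, and the significance levels the pooled t-test reproduces.
C3_PREP = [-0.45044, -0.31794, -0.56522]
C3_EXEC = [-0.94739, -1.0896, -1.6016]
C4_PREP = [0.026749, -0.047736, 0.20375]
C4_EXEC = [-0.51328, -0.34357, -0.15104]


@pytest.mark.parametrize("a, b, p_expected", [
    (C3_PREP, C3_EXEC, 0.021975815),
    (C4_PREP, C4_EXEC, 0.036622313),
])
def test_ttest_reproduces_published_significance(a, b, p_expected):
    t, p = mf.erd_ttest(a, b)
    assert p == pytest.approx(p_expected, abs=1e-8)
    assert t > 0  # preparation-period ERD is less negative


def test_ttest_identical_groups_null():
    t, p = mf.erd_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_ttest_degenerate_inputs():
    with pytest.raises(mf.ConfigurationError):
        mf.erd_ttest([1.0], [1.0, 2.0])
    with pytest.raises(mf.DegenerateSignalError):
        mf.erd_ttest([1.0, 1.0], [2.0, 2.0])
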