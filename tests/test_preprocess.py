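"""Filtering, resampling and epoching contracts."""

import numpy as np
import pytest

import mifatigue as mf


def tone(freq, fs=1024.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    data = amp * np.sin(2 * np.pi * freq * t)[None, :]
    return mf.Recording(data=data.astype(np.float32), fs=fs, labels=("C3",))


def interior_rms(x, fs, margin_s=2.0):
    m = int(margin_s * fs)
    return np.sqrt(np.mean(x[m:-m] ** 2))


def test_passband_tone_preserved():
    rec = tone(10.0)
    out = mf.bandpass(rec)
    ratio = interior_rms(out.data[0], rec.fs) / interior_rms(rec.data[0], rec.fs)
    assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)  # within 1 dB


def test_line_frequency_suppressed():
    rec = tone(50.0)
    out = mf.bandpass(rec)
    ratio = interior_rms(out.data[0], rec.fs) / interior_rms(rec.data[0], rec.fs)
    assert ratio <= 0.01


def test_dc_offset_removed():
    rec = tone(10.0)
    rec.data += 5.0
    out = mf.bandpass(rec)
    # DC sits deep in the stopband: residual below 1% of the 5 uV offset
    assert abs(out.data[0, 2048:-2048].mean()) < 0.05


def test_cutoff_above_nyquist_rejected():
    with pytest.raises(mf.ConfigurationError):
        mf.bandpass(tone(10.0, fs=64.0), 1.0, 35.0)


def test_resample_identity():
    rec = tone(10.0)
    out = mf.resample(rec, rec.fs)
    assert np.array_equal(out.data, rec.data)


def test_resample_matches_analytic_sine():
    rec = tone(10.0, fs=1024.0)
    out = mf.resample(rec, 512.0)
    t = np.arange(out.n_samples) / 512.0
    ref = np.sin(2 * np.pi * 10.0 * t)
    sl = slice(512, -512)
    r = np.corrcoef(out.data[0, sl], ref[sl])[0, 1]
    assert r > 0.999


def test_resample_rescales_events():
    rec = tone(10.0)
    rec.events.append(mf.Event(sample=1024, trial=0, label=mf.LEFT))
    out = mf.resample(rec, 512.0)
    assert out.events[0].sample == 512


def test_epoch_counts_and_baseline(small_recording):
    ep = mf.epoch(small_recording)
    assert ep.n_trials == len(small_recording.events)
    assert ep.data.shape[2] == int(5 * small_recording.fs)
    t0 = ep.window[0]
    bl = slice(0, int(small_recording.fs))
    assert np.allclose(ep.data[:, :, bl].mean(axis=2), 0.0, atol=1e-3)


def test_constant_channel_epochs_to_zero():
    fs = 256.0
    data = np.full((1, int(20 * fs)), 7.0, dtype=np.float32)
    rec = mf.Recording(data=data, fs=fs, labels=("Cz",),
                       events=[mf.Event(int(8 * fs), 0, mf.LEFT)])
    ep = mf.epoch(rec)
    assert np.allclose(ep.data, 0.0)


def test_baseline_removal_idempotent(small_epochs):
    again = mf.remove_baseline(small_epochs)
    assert np.allclose(again.data, small_epochs.data, atol=1e-4)


def test_epoch_out_of_bounds_lists_trials():
    fs = 256.0
    data = np.zeros((1, int(6 * fs)), dtype=np.float32)
    rec = mf.Recording(data=data, fs=fs, labels=("Cz",),
                       events=[mf.Event(int(4 * fs), 3, mf.LEFT)])
    with pytest.raises(mf.ConfigurationError, match="3"):
        mf.epoch(rec)


def test_filter_then_epoch_commutes_on_interior():
    """Filtering the session then epoching equals filtering a margin-
    extended segment then cropping, away from segment edges."""
    rng = np.random.default_rng(0)
    fs = 1024.0
    data = rng.standard_normal((1, int(24 * fs))).astype(np.float32)
    ev = mf.Event(int(10 * fs), 0, mf.LEFT)
    rec = mf.Recording(data=data, fs=fs, labels=("C3",), events=[ev])

    whole = mf.epoch(mf.bandpass(rec), window=(0.0, 5.0))
    margin = 4.0
    seg = data[:, ev.sample - int(margin * fs) : ev.sample + int((5 + margin) * fs)]
    seg_rec = mf.Recording(data=seg, fs=fs, labels=("C3",),
                           events=[mf.Event(int(margin * fs), 0, mf.LEFT)])
    pieced = mf.epoch(mf.bandpass(seg_rec), window=(0.0, 5.0))
    np.testing.assert_allclose(
        whole.data[0, 0], pieced.data[0, 0], rtol=1e-5, atol=1e-5
    )


def test_clean_epochs_passthrough(small_epochs):
    assert mf.clean_epochs(small_epochs) is small_epochs
    with pytest.raises(mf.ConfigurationError):
        mf.clean_epochs(small_epochs, method="ica")
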