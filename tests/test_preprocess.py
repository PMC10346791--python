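"""Filtering, montage, resampling, segmentation, and pipeline properties."""

import numpy as np
import pytest
from scipy import signal as sps

from eegwavenet.errors import MontageError, ParameterError, TooShortError
from eegwavenet.preprocess import (
    BANDPASS_05_49, HIGHPASS_1HZ, NOTCH_60HZ, TCP_20, FilterSpec,
    apply_filter, derive_tcp_montage, extract_segments, preprocess_pipeline,
    resample, standardize,
)
from eegwavenet.recordings import Recording
from eegwavenet.synthetic import ELECTRODES_21, SyntheticSpec, simulate_recording

from conftest import make_recording


def _sine_recording(freq, fs, duration=10.0, label="C3"):
    t = np.arange(int(duration * fs)) / fs
    return Recording(signal=np.sin(2 * np.pi * freq * t)[None, :],
                     fs=fs, labels=[label])


# --------------------------------------------------------------------------
# filters


def test_highpass_removes_dc():
    rec = Recording(signal=np.full((1, 2500), 100.0), fs=250, labels=["C3"])
    out = apply_filter(rec, HIGHPASS_1HZ)
    inner = out.signal[0, 500:-500]  # discard 2 s edges
    assert np.abs(inner).max() < 1e-6 * 100.0


def test_notch_attenuation_matches_transfer_function():
    """Measured 60 Hz suppression agrees with |H(60)|^2 from the designed
    filter's frequency response (zero-phase doubles the attenuation)."""
    fs = 250.0
    rec = _sine_recording(60.0, fs)
    out = apply_filter(rec, NOTCH_60HZ)
    mid = slice(500, -500)
    rms_ratio = np.std(out.signal[0, mid]) / np.std(rec.signal[0, mid])
    assert rms_ratio < 0.05
    b, a = sps.iirnotch(60.0, 30.0, fs=fs)
    _, h = sps.freqz(b, a, worN=[60.0], fs=fs)
    assert rms_ratio == pytest.approx(np.abs(h[0]) ** 2, abs=0.02)


def test_highpass_passband_flat_at_10hz():
    """|H(10)|^2 for a 4th-order 1 Hz Butterworth is within 1% of unity."""
    rec = _sine_recording(10.0, 250.0)
    out = apply_filter(rec, HIGHPASS_1HZ)
    mid = slice(500, -500)
    rms_ratio = np.std(out.signal[0, mid]) / np.std(rec.signal[0, mid])
    expected = (1 + (1 / 10) ** 8) ** -1  # single-pass magnitude, squared
    assert rms_ratio == pytest.approx(1.0, abs=0.01)
    assert rms_ratio == pytest.approx(expected, abs=0.005)


def test_filter_cutoff_validation():
    with pytest.raises(ParameterError) as exc:
        apply_filter(_sine_recording(10, 100.0),
                     FilterSpec("highpass", (60.0,)))
    assert "60" in str(exc.value)
    with pytest.raises(ParameterError):
        FilterSpec("bandpass", (30.0, 10.0))
    with pytest.raises(ParameterError):
        FilterSpec("nonsense", (1.0,))


def test_zero_phase_no_group_delay(rng):
    """A band-limited pulse keeps its cross-correlation peak at lag 0."""
    fs = 250.0
    t = np.arange(int(4 * fs)) / fs
    pulse = np.exp(-0.5 * ((t - 2.0) / 0.15) ** 2) * np.sin(2 * np.pi * 8 * t)
    rec = Recording(signal=pulse[None, :], fs=fs, labels=["C3"])
    out = apply_filter(rec, BANDPASS_05_49)
    xc = np.correlate(out.signal[0], rec.signal[0], mode="full")
    assert np.argmax(xc) == len(pulse) - 1  # zero lag


# --------------------------------------------------------------------------
# montage


def test_tcp_montage_shape_and_first_channel(rng):
    rec = make_recording(rng)
    out = derive_tcp_montage(rec, TCP_20)
    assert out.n_channels == 20
    assert out.labels[0] == "FP1-F7"
    i_fp1 = rec.labels.index("FP1")
    i_f7 = rec.labels.index("F7")
    np.testing.assert_array_equal(out.signal[0],
                                  rec.signal[i_fp1] - rec.signal[i_f7])
    for i, (a, c) in enumerate(TCP_20.pairs):
        np.testing.assert_array_equal(
            out.signal[i],
            rec.signal[rec.labels.index(a)] - rec.signal[rec.labels.index(c)])


def test_tcp_montage_identical_signals_zero(rng):
    base = rng.standard_normal(1000)
    sig = np.tile(base, (21, 1))
    rec = Recording(signal=sig, fs=250, labels=list(ELECTRODES_21))
    out = derive_tcp_montage(rec, TCP_20)
    assert np.abs(out.signal).max() == 0.0


def test_tcp_montage_missing_electrode_lists_all(rng):
    labels = [l for l in ELECTRODES_21 if l not in ("T3", "O2")]
    rec = make_recording(rng, labels=labels)
    with pytest.raises(MontageError) as exc:
        derive_tcp_montage(rec, TCP_20)
    assert "T3" in str(exc.value) and "O2" in str(exc.value)


def test_montage_linearity(rng):
    x = make_recording(rng)
    y = make_recording(rng)
    a, b = 1.7, -0.3
    combo = x.with_signal(a * x.signal + b * y.signal)
    lhs = derive_tcp_montage(combo).signal
    rhs = a * derive_tcp_montage(x).signal + b * derive_tcp_montage(y).signal
    np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


def test_filter_montage_commute(rng):
    rec = make_recording(rng, duration=6.0)
    fm = derive_tcp_montage(apply_filter(rec, HIGHPASS_1HZ))
    mf = apply_filter(derive_tcp_montage(rec), HIGHPASS_1HZ)
    scale = np.abs(fm.signal).max()
    np.testing.assert_allclose(fm.signal, mf.signal, atol=1e-8 * scale)


# --------------------------------------------------------------------------
# resampling


def test_resample_length_and_identity(rng):
    rec = make_recording(rng, fs=500.0, duration=10.0)
    out = resample(rec, 250.0)
    assert out.n_samples == 2500
    assert out.fs == 250.0
    same = resample(rec, 500.0)
    assert same.signal is rec.signal  # bit-identical, no copy

    half = resample(out, 125.0)
    assert half.n_samples == 1250


def test_resample_preserves_tone_frequency():
    rec = _sine_recording(10.0, 1000.0, duration=8.0)
    out = resample(rec, 250.0)
    f, pxx = sps.periodogram(out.signal[0], fs=out.fs)
    assert abs(f[np.argmax(pxx)] - 10.0) <= 0.5


# --------------------------------------------------------------------------
# segments


def test_extract_segments_with_reversal(rng):
    rec = make_recording(rng, fs=250.0, duration=130.0)
    segs = extract_segments(rec, 60.0, augment_reverse=True)
    assert segs.data.shape == (2, 21, 15000)
    assert segs.provenance == ["original", "reversed"]
    np.testing.assert_array_equal(segs.data[0], rec.signal[:, :15000])
    np.testing.assert_array_equal(segs.data[1],
                                  rec.signal[:, 15000:30000][:, ::-1])
    # involution: reversing the reversed segment recovers [15000, 30000)
    np.testing.assert_array_equal(segs.data[1][:, ::-1],
                                  rec.signal[:, 15000:30000])


def test_extract_segments_short_recording(rng):
    rec = make_recording(rng, fs=250.0, duration=90.0)
    segs = extract_segments(rec, 60.0, augment_reverse=True)
    assert len(segs) == 1 and segs.provenance == ["original"]
    with pytest.raises(TooShortError):
        extract_segments(make_recording(rng, duration=50.0), 60.0)


def test_time_reversal_preserves_moments(rng):
    rec = make_recording(rng, fs=250.0, duration=8.0)
    segs = extract_segments(rec, 4.0, augment_reverse=True)
    orig_src = rec.signal[:, 1000:2000]
    # the reversed segment is a permutation: identical sample multiset,
    # and moments agree to floating-point summation-order tolerance
    np.testing.assert_array_equal(np.sort(segs.data[1], axis=1),
                                  np.sort(orig_src, axis=1))
    np.testing.assert_allclose(segs.data[1].mean(axis=1),
                               orig_src.mean(axis=1), rtol=0, atol=1e-10)
    np.testing.assert_allclose(segs.data[1].std(axis=1),
                               orig_src.std(axis=1), rtol=1e-10)


def test_standardize(rng):
    rec = make_recording(rng, fs=250.0, duration=8.0)
    segs = extract_segments(rec, 4.0)
    out = standardize(segs)
    np.testing.assert_allclose(out.data.mean(axis=2), 0.0, atol=1e-9)
    np.testing.assert_allclose(out.data.std(axis=2), 1.0, rtol=1e-6)
    again = standardize(out)
    np.testing.assert_allclose(again.data, out.data, atol=1e-12)


def test_standardize_zero_variance_guard():
    segs = extract_segments(
        Recording(signal=np.zeros((1, 1000)), fs=250, labels=["C3"]), 2.0)
    with pytest.warns(RuntimeWarning):
        out = standardize(segs)
    assert np.all(out.data == 0.0)


# --------------------------------------------------------------------------
# pipeline profiles


def test_tuab_pipeline_shapes():
    spec = SyntheticSpec(fs=500.0, duration=130.0, seed=11)
    rec, _ = simulate_recording(spec, "normal", 0)
    segs = preprocess_pipeline(rec, profile="tuab")
    assert segs.data.shape == (2, 20, 15000)
    assert segs.fs == 250.0
    assert segs.labels == ["normal", "normal"]
    assert segs.channel_names[0] == "FP1-F7"
    np.testing.assert_allclose(segs.data.std(axis=2), 1.0, rtol=1e-6)


def test_tuep_pipeline_shapes(rng):
    labels = list(ELECTRODES_21) + [f"X{i}" for i in range(10)]
    rec = make_recording(rng, fs=500.0, duration=40.0, labels=labels)
    segs = preprocess_pipeline(rec, profile="tuep")
    assert segs.data.shape == (1, 30, 7500)
    assert segs.provenance == ["original"]


def test_pipeline_errors(rng):
    short = make_recording(rng, fs=250.0, duration=50.0)
    with pytest.raises(TooShortError):
        preprocess_pipeline(short, profile="tuab")
    with pytest.raises(ParameterError):
        preprocess_pipeline(short, profile="tuep")  # only 21 channels
    with pytest.raises(ParameterError):
        preprocess_pipeline(short, profile="nope")
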