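"""LFP preprocessing, band intensity, spectra, event detection, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from cephalosleep.datatypes import LFPRecording, StateSchedule
from cephalosleep.ephys import (
    HIGH_BAND, LOW_BAND, BandSpec, band_intensity, detect_osc_events,
    extract_state_segments, fraction_near_flashes, intensity_correlation,
    multitaper_spectrum, preprocess_lfp, qs_chunks_before_bouts,
    region_aggregate, wavelet_spectrogram,
)
from conftest import make_channel_table


# --------------------------------------------------------------------------- #
# preprocessing

def test_common_mode_cancels_exactly():
    """A signal identical on all channels is removed to machine precision."""
    rng = np.random.default_rng(0)
    fs = 2500.0
    common = rng.normal(0, 50, int(10 * fs))
    data = np.tile(common, (6, 1))
    rec = LFPRecording(data, fs, make_channel_table(6, n_out=2))
    pre = preprocess_lfp(rec)
    rms = np.sqrt((pre.data[:4] ** 2).mean())
    assert rms < 1e-9


def _lockin_amp(y, f0, fs, trim=5000):
    """Amplitude of the f0 component (lock-in), ignoring filter transients."""
    y = y[trim:-trim]
    t = np.arange(y.size) / fs
    return 2 * np.abs(np.mean(y * np.exp(-2j * np.pi * f0 * t)))


def _chain_gain(f0):
    """Zero-phase gain of the designed 0.1-150 Hz 3-pole bandpass at f0."""
    sos = signal.butter(3, (0.1, 150.0), btype="bandpass", fs=1000.0, output="sos")
    _, h = signal.sosfreqz(sos, worN=[f0], fs=1000.0)
    return np.abs(h[0]) ** 2


def test_in_band_tone_gain_matches_filter_response():
    """In-band gain agrees with the designed filter chain's own response."""
    fs = 2500.0
    t = np.arange(int(30 * fs)) / fs
    for f0 in (20.0, 100.0):
        data = np.tile(50.0 * np.sin(2 * np.pi * f0 * t), (3, 1))
        data[2] = 0.0
        rec = LFPRecording(data, fs, make_channel_table(3))
        pre = preprocess_lfp(rec)
        amp = _lockin_amp(pre.data[0], f0, 1000.0)
        assert amp == pytest.approx(50.0 * _chain_gain(f0), rel=0.02)
        if f0 == 20.0:
            assert amp == pytest.approx(50.0, rel=0.02)


def test_stopband_tone_attenuated():
    """A 200 Hz tone is strongly attenuated, consistent with the 3-pole design."""
    fs = 2500.0
    t = np.arange(int(20 * fs)) / fs
    data = np.tile(50.0 * np.sin(2 * np.pi * 200.0 * t), (3, 1))
    data[2] = 0.0
    rec = LFPRecording(data, fs, make_channel_table(3))
    pre = preprocess_lfp(rec)
    amp = _lockin_amp(pre.data[0], 200.0, 1000.0)
    db = 20 * np.log10(amp / 50.0)
    assert db < -15.0  # three-pole zero-phase: ~-19.5 dB at 200 Hz
    assert abs(db - 20 * np.log10(_chain_gain(200.0))) < 1.0


def test_preprocess_requires_oob_channels_and_lfp_rate():
    rec = LFPRecording(np.zeros((3, 1000)), 2500.0, make_channel_table(3, n_out=0))
    with pytest.raises(ValueError):
        preprocess_lfp(rec)
    rec2 = LFPRecording(np.zeros((3, 1000)), 200.0, make_channel_table(3))
    with pytest.raises(ValueError):
        preprocess_lfp(rec2)


# --------------------------------------------------------------------------- #
# segments

def test_segment_windows(simple_schedule):
    rec = LFPRecording(np.zeros((3, int(700 * 1000))), 1000.0, make_channel_table(3))
    segs = extract_state_segments(rec, simple_schedule, flash_times=[100.0])
    assert (240.0, 300.0) in segs.segments["QS"]
    assert (300.0, 360.0) in segs.segments["AS"]
    assert segs.segments["flash"][0] == (pytest.approx(99.65), pytest.approx(100.35))


def test_segment_out_of_bounds_dropped():
    sched = StateSchedule([("QS", 0, 680), ("AS", 680, 700)])
    rec = LFPRecording(np.zeros((3, int(700 * 1000))), 1000.0, make_channel_table(3))
    with pytest.warns(UserWarning):
        segs = extract_state_segments(rec, sched)
    assert segs.segments["AS"] == []   # 680+60 exceeds record
    assert segs.n_dropped == 1


def test_qs_overlapping_wake_removed():
    sched = StateSchedule([("wake", 230, 250), ("AS", 300, 360)])
    rec = LFPRecording(np.zeros((3, int(700 * 1000))), 1000.0, make_channel_table(3))
    with pytest.warns(UserWarning):
        segs = extract_state_segments(rec, sched)
    assert segs.segments["QS"] == []


# --------------------------------------------------------------------------- #
# band intensity

def test_band_intensity_zero_signal():
    rec = LFPRecording(np.zeros((4, 60000)), 1000.0, make_channel_table(4))
    out = band_intensity(rec, [(0, 60)], LOW_BAND)
    assert np.allclose(out, 0.0)


def test_band_intensity_tone_amplitude(tone_recording):
    """A 5 Hz tone of amplitude 50 uV reads 50 uV in the low band, <5% leakage."""
    low = band_intensity(tone_recording, [(0, 60)], LOW_BAND)
    high = band_intensity(tone_recording, [(0, 60)], HIGH_BAND)
    assert np.all(np.abs(low - 50.0) < 0.05 * 50.0)
    assert np.all(high <= 0.05 * 50.0)


def test_band_intensity_median_filter_suppresses_outlier_channel():
    rng = np.random.default_rng(1)
    fs = 1000.0
    data = rng.normal(0, 10, (9, int(30 * fs)))
    data[4] *= 100.0
    rec = LFPRecording(data, fs, make_channel_table(9))
    out = band_intensity(rec, [(0, 30)], HIGH_BAND)
    assert out[4] < 3 * np.median(out)


def test_band_intensity_short_segments_dropped():
    rec = LFPRecording(np.zeros((3, 60000)), 1000.0, make_channel_table(3))
    with pytest.raises(ValueError):
        band_intensity(rec, [(0, 0.1)], LOW_BAND)


# --------------------------------------------------------------------------- #
# spectra

def test_spectrogram_normalized_to_unit_max():
    rng = np.random.default_rng(2)
    mag, freqs = wavelet_spectrogram(rng.normal(0, 1, 2000), fs=1000.0)
    assert mag.max() == pytest.approx(1.0)
    assert mag.shape == (100, 2000)
    assert freqs[0] == pytest.approx(1.0) and freqs[-1] == pytest.approx(100.0)


def test_spectrogram_localizes_tone():
    fs = 1000.0
    t = np.arange(int(4 * fs)) / fs
    mag, freqs = wavelet_spectrogram(np.sin(2 * np.pi * 30 * t), fs)
    row = mag.mean(axis=1).argmax()
    step = freqs[1] / freqs[0]
    assert freqs[row] / step <= 30.0 <= freqs[row] * step


def test_spectrogram_two_tones_two_maxima():
    fs = 1000.0
    t = np.arange(int(4 * fs)) / fs
    x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 50 * t)
    mag, freqs = wavelet_spectrogram(x, fs)
    profile = mag.mean(axis=1)
    for f0 in (5.0, 50.0):
        i = np.argmin(np.abs(freqs - f0))
        lo, hi = max(i - 3, 0), min(i + 4, profile.size)
        j = lo + profile[lo:hi].argmax()
        assert profile[j] > 0.9 * profile[np.argmin(np.abs(freqs - f0))]
        # a local maximum exists near the tone row
        assert profile[j] >= profile[max(j - 4, 0)] and profile[j] >= profile[min(j + 4, profile.size - 1)]


def test_spectrogram_empty_raises():
    with pytest.raises(ValueError):
        wavelet_spectrogram(np.array([]), 1000.0)


def test_multitaper_parseval_white_noise():
    rng = np.random.default_rng(3)
    fs = 1000.0
    x = rng.normal(0, 2.0, int(60 * fs))
    freqs, psd = multitaper_spectrum(x, fs)
    integral = psd.sum() * (freqs[1] - freqs[0])
    assert integral == pytest.approx(4.0, rel=0.10)


def test_multitaper_tone_peak():
    rng = np.random.default_rng(4)
    fs = 1000.0
    t = np.arange(int(30 * fs)) / fs
    x = np.sin(2 * np.pi * 20 * t) + rng.normal(0, 0.5, t.size)
    freqs, psd = multitaper_spectrum(x, fs)
    assert abs(freqs[psd.argmax()] - 20.0) <= 1.0


def test_multitaper_partial_chunk_discarded():
    rng = np.random.default_rng(5)
    fs = 1000.0
    x = rng.normal(0, 1, int(1.9 * fs))
    f1, p1 = multitaper_spectrum(x, fs)
    f2, p2 = multitaper_spectrum(x[:int(fs)], fs)
    assert np.array_equal(p1, p2)


# --------------------------------------------------------------------------- #
# oscillatory events

def test_osc_events_zero_signal():
    rec = LFPRecording(np.zeros((3, 60000)), 1000.0, make_channel_table(3))
    ev = detect_osc_events(rec, [(0, 60)])
    assert all(t.size == 0 for t in ev.times)
    assert np.allclose(ev.rate_hz, 0)


def test_injected_bursts_recovered_with_timing():
    """20 bursts at 6x the broadband QS noise SD: all recovered within 0.1 s."""
    from cephalosleep.simulate import LFPSimConfig, gen_lfp
    from conftest import match_events

    sched = StateSchedule([("QS", 0, 610)])
    cfg = LFPSimConfig(n_channels=4, fs_Hz=1000.0, n_out_of_brain=1,
                       out_of_brain_channels=(3,), spindle_channels=(), seed=0)
    rec, _ = gen_lfp(cfg, sched)
    pre = preprocess_lfp(rec)
    x = pre.data[0]
    amp = 6 * x[:600000].std()
    rng = np.random.default_rng(10)
    times = np.sort(rng.uniform(10, 590, 20))
    while np.any(np.diff(times) < 2.0):
        times = np.sort(rng.uniform(10, 590, 20))
    for t in times:
        m = 500
        i0 = int((t - 0.25) * 1000)
        tau = np.arange(m) / 1000.0
        hann = 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / (m - 1)))
        x[i0:i0 + m] += amp * hann * np.sin(2 * np.pi * 15 * tau)
    ev = detect_osc_events(pre, [(0, 600)])
    det = ev.times[0]
    assert abs(det.size - 20) <= 1
    assert match_events(det, times, tol_s=0.1) >= 19


def test_qs_chunks_remove_wake():
    sched = StateSchedule([("AS", 1300, 1360), ("wake", 500, 600)])
    chunks = qs_chunks_before_bouts(sched, duration_s=1400, window_s=1200)
    assert chunks == [(100, 500), (600, 1300)]


def test_fraction_near_flashes_hand_count():
    assert fraction_near_flashes([5.0, 30.0], [10.0]) == pytest.approx(0.5)
    assert fraction_near_flashes([5.0, 30.0], []) == 0.0
    with pytest.raises(ValueError):
        fraction_near_flashes([], [10.0])


def test_fraction_near_flashes_independent_poisson():
    """Independent events/flashes: coverage ~ 1 - exp(-2 w lambda_f)."""
    rng = np.random.default_rng(6)
    T, lam_f, w = 20000.0, 0.01, 10.0
    events = np.sort(rng.uniform(0, T, 800))
    flashes = np.sort(rng.uniform(0, T, int(lam_f * T)))
    frac = fraction_near_flashes(events, flashes, w)
    p = 1 - np.exp(-2 * w * lam_f)
    sem = np.sqrt(p * (1 - p) / events.size)
    assert abs(frac - p) < 3 * sem + 0.01


# --------------------------------------------------------------------------- #
# region aggregation and correlation

def _channels_for_regions():
    return pd.DataFrame({
        "x_um": np.zeros(8),
        "y_um": [10.0, 15.0, 25.0, 30.0, 5.0, 8.0, 40.0, 45.0],
        "z_um": np.zeros(8),
        "region": ["VL", "VL", "VL", "VL", "sFL", "sFL", "Buc", "Buc"],
        "in_brain": [True] * 8,
        "probe": [0, 0, 1, 1, 0, 1, 0, 0],
    })


def test_region_aggregate_constant_map():
    ch = _channels_for_regions()
    out = region_aggregate(np.full(8, 3.5), ch)
    assert set(out.index) == {"VL", "sFL"}     # Buc has one probe only
    assert np.allclose(out["mean"], 3.5)


def test_region_aggregate_excludes_single_probe_regions():
    ch = _channels_for_regions()
    out = region_aggregate(np.arange(8.0), ch, min_probes=2)
    assert "Buc" not in out.index


def test_region_aggregate_ap_split_midpoint():
    ch = _channels_for_regions()
    out = region_aggregate(np.arange(8.0), ch, split_ap=True)
    # VL spans 10-30, midpoint 20: channels at 10,15 anterior; 25,30 posterior
    assert out.loc["VL-anterior", "mean"] == pytest.approx(0.5)
    assert out.loc["VL-posterior", "mean"] == pytest.approx(2.5)


def test_region_aggregate_unknown_region_raises():
    ch = _channels_for_regions()
    with pytest.raises(ValueError, match="unknown region"):
        region_aggregate(np.zeros(8), ch, valid_regions=["VL", "sFL"])


def test_intensity_correlation_affine_and_sign():
    rng = np.random.default_rng(7)
    a = rng.normal(0, 1, 50)
    assert intensity_correlation(a, 2 * a + 1) == pytest.approx(1.0)
    assert intensity_correlation(a, -a) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        intensity_correlation(a, np.zeros(50))


def test_intensity_correlation_null():
    rng = np.random.default_rng(8)
    rs = [intensity_correlation(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
          for _ in range(200)]
    assert abs(np.mean(rs)) < 0.01


def test_end_to_end_state_ordering_in_region_summary():
    """QS < wake < AS band power ordering survives the full pipeline."""
    from cephalosleep.simulate import LFPSimConfig, gen_lfp

    sched = StateSchedule([("QS", 0, 60), ("AS", 60, 120), ("wake", 120, 180),
                           ("QS", 180, 240)])
    cfg = LFPSimConfig(n_channels=16, fs_Hz=1000.0, n_out_of_brain=2,
                       out_of_brain_channels=(14, 15), spindle_channels=(), seed=0)
    rec, _ = gen_lfp(cfg, sched)
    pre = preprocess_lfp(rec)
    means = {}
    for state, seg in [("QS", (0, 60)), ("AS", (60, 120)), ("wake", (120, 180))]:
        vals = band_intensity(pre, [seg], HIGH_BAND)
        summ = region_aggregate(vals, pre.channels)
        means[state] = summ["mean"].mean()
    assert means["QS"] < means["wake"] < means["AS"]
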