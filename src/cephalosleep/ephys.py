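"""Multi-channel LFP analysis: preprocessing, state-dependent band intensity,
spectra, quiet-sleep oscillatory (spindle-like) event detection, and
atlas-region aggregation.

Pipeline conventions: raw recordings are resampled to 1 kHz, bandpassed
0.1-150 Hz and re-referenced by subtracting the per-sample median of the
out-of-brain channel set (which removes any signal common to all channels
exactly).  Band intensities are mean analytic envelopes, median-filtered over
a 5-channel window along the probe to suppress single bad channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats
from scipy.ndimage import median_filter

from .datatypes import LFPRecording, StateSchedule

__all__ = [
    "BandSpec",
    "LOW_BAND",
    "HIGH_BAND",
    "OscEventParams",
    "preprocess_lfp",
    "extract_state_segments",
    "SegmentSet",
    "band_intensity",
    "wavelet_spectrogram",
    "multitaper_spectrum",
    "detect_osc_events",
    "qs_chunks_before_bouts",
    "fraction_near_flashes",
    "region_aggregate",
    "intensity_correlation",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo_Hz: float
    hi_Hz: float

    def validate(self, fs: float):
        if not (0 < self.lo_Hz < self.hi_Hz < fs / 2):
            raise ValueError(f"band {self.name} ({self.lo_Hz}-{self.hi_Hz} Hz) "
                             f"infeasible at fs={fs}")


LOW_BAND = BandSpec("low", 0.1, 10.0)
HIGH_BAND = BandSpec("high", 20.0, 150.0)


@dataclass
class OscEventParams:
    """QS oscillatory-event detection: 4-40 Hz bandpass, peaks on the
    per-segment z-scored signal with height 2 z, prominence 2 z, 1-s
    separation; rates averaged over 1200-s QS chunks."""

    band_Hz: tuple = (4.0, 40.0)
    min_height_z: float = 2.0
    min_prominence_z: float = 2.0
    min_separation_s: float = 1.0
    qs_window_s: float = 1200.0
    flash_window_s: float = 0.7
    median_channels: int = 5


def _butter_sos(poles, cutoff, btype, fs):
    return signal.butter(poles, cutoff, btype=btype, fs=fs, output="sos")


def _filtfilt(sos, x, axis=-1):
    padlen = min(3 * (2 * sos.shape[0] + 1), x.shape[axis] - 1)
    return signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


# --------------------------------------------------------------------------- #
# preprocessing

def preprocess_lfp(rec: LFPRecording, target_fs: float = 1000.0) -> LFPRecording:
    """Resample to 1 kHz, bandpass 0.1-150 Hz, median re-reference.

    The per-sample median over the out-of-brain channel set is subtracted
    from every channel; any component common to all channels cancels
    exactly.  Channels are processed independently, so identical inputs
    produce identical outputs.
    """
    if rec.fs_Hz < 300:
        raise ValueError("sampling rate below 300 Hz; not an LFP-band recording")
    oob = rec.out_of_brain_indices()
    if oob.size == 0:
        raise ValueError("no out-of-brain channels available for re-referencing")

    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs_Hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    n_out = int(np.ceil(rec.n_samples * up / down))
    sos = _butter_sos(3, (0.1, min(150.0, target_fs / 2 * 0.99)), "bandpass", target_fs)

    out = np.empty((rec.n_channels, n_out), dtype=np.float64)
    for c in range(rec.n_channels):
        x = rec.data[c].astype(np.float64)
        if (up, down) != (1, 1):
            x = signal.resample_poly(x, up, down)
        out[c] = _filtfilt(sos, x)
    out -= np.median(out[oob], axis=0)
    return LFPRecording(data=out, fs_Hz=target_fs, channels=rec.channels.copy())


# --------------------------------------------------------------------------- #
# state segments

class SegmentSet(NamedTuple):
    segments: dict            # label -> list of (start_s, end_s)
    n_dropped: int


def extract_state_segments(
    rec: LFPRecording,
    schedule: StateSchedule,
    flash_times: Sequence[float] = (),
    window_s: float = 60.0,
    flash_window_s: float = 0.7,
) -> SegmentSet:
    """Fixed-length analysis segments per behavioural state.

    AS and wake segments are ``window_s`` seconds from each labelled onset;
    QS segments are the ``window_s`` seconds immediately *preceding* each AS
    onset (QS overlapping a wake interval is removed); flash segments are
    ``flash_window_s`` centred on flash times.  Segments exceeding the
    record bounds are dropped with a warning.
    """
    T = rec.duration_s
    dropped = 0
    segs: dict[str, list[tuple[float, float]]] = {"AS": [], "QS": [], "wake": [], "flash": []}

    def _add(label, s, e):
        nonlocal dropped
        if s < 0 or e > T:
            dropped += 1
            return
        segs[label].append((s, e))

    wake_ivs = schedule.by_label("wake")
    for label in ("AS", "wake"):
        for onset in schedule.onsets(label):
            _add(label, onset, onset + window_s)
    for onset in schedule.onsets("AS"):
        s, e = onset - window_s, onset
        if any(ws < e and we > s for ws, we in wake_ivs):
            dropped += 1
            continue
        _add("QS", s, e)
    for t in flash_times:
        _add("flash", t - flash_window_s / 2, t + flash_window_s / 2)
    if dropped:
        warnings.warn(f"dropped {dropped} segments exceeding record bounds or "
                      "overlapping wake", stacklevel=2)
    return SegmentSet(segs, dropped)


def _slice(rec: LFPRecording, seg: tuple[float, float]) -> np.ndarray:
    i0 = int(round(seg[0] * rec.fs_Hz))
    i1 = int(round(seg[1] * rec.fs_Hz))
    return rec.data[:, max(i0, 0):min(i1, rec.n_samples)]


# --------------------------------------------------------------------------- #
# band intensity

def hilbert_fir(numtaps: int = 151) -> np.ndarray:
    """Odd-length (type III) FIR Hilbert transformer.

    Accurate above ~10 Hz at 1 kHz sampling; the default envelope path uses
    the FFT analytic signal instead, which is exact for in-band tones down to
    the lowest analysis frequencies.
    """
    return signal.remez(numtaps, [0.01, 0.49], [1.0], type="hilbert", fs=1.0)


def _envelope(x: np.ndarray, method: str, taps: int) -> np.ndarray:
    if method == "fft":
        return np.abs(signal.hilbert(x, axis=-1))
    if method == "fir":
        h = hilbert_fir(taps)
        quad = np.apply_along_axis(lambda v: np.convolve(v, h, mode="same"), -1, x)
        return np.hypot(x, quad)
    raise ValueError(f"unknown envelope method {method!r}")


def band_intensity(
    rec: LFPRecording,
    segments: Sequence[tuple[float, float]],
    band: BandSpec,
    median_channels: int = 5,
    envelope: str = "fft",
    fir_taps: int = 151,
    filter_poles: int = 3,
) -> np.ndarray:
    """Per-channel band intensity (microvolts) averaged over segments.

    Per segment and channel: bandpass, analytic envelope, mean over time;
    a ``median_channels``-point sliding median across the channel axis then
    suppresses isolated bad channels (edge channels use shrunken windows),
    and the result is averaged over segments.  Segments shorter than twice
    the FIR length are dropped.
    """
    if not segments:
        raise ValueError("need at least one segment")
    band.validate(rec.fs_Hz)
    sos = _butter_sos(filter_poles, (band.lo_Hz, band.hi_Hz), "bandpass", rec.fs_Hz)
    min_len = 2 * fir_taps
    per_seg = []
    for seg in segments:
        x = _slice(rec, seg)
        if x.shape[1] < min_len:
            continue
        xf = _filtfilt(sos, x.astype(np.float64))
        env = _envelope(xf, envelope, fir_taps)
        mean_env = env.mean(axis=1)
        per_seg.append(median_filter(mean_env, size=median_channels, mode="nearest"))
    if not per_seg:
        raise ValueError("all segments shorter than the filter warm-up")
    return np.mean(per_seg, axis=0)


# --------------------------------------------------------------------------- #
# spectra

def wavelet_spectrogram(
    x: np.ndarray,
    fs: float,
    fmin: float = 1.0,
    fmax: float = 100.0,
    n_freqs: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised complex-Morlet scalogram.

    Complex Morlet (bandwidth 1.5, centre frequency 1.0), 100 log-spaced
    frequencies in [1, 100] Hz; magnitudes divided by their maximum so the
    output lies in [0, 1].  Returns ``(magnitude [n_freqs, n_samples],
    freqs_Hz)`` with frequencies ascending.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < fs:
        raise ValueError("need at least 1 s of signal")
    freqs = np.logspace(np.log10(fmin), np.log10(fmax), n_freqs)
    fc = pywt.central_frequency("cmor1.5-1.0")
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(x, scales, "cmor1.5-1.0", sampling_period=1.0 / fs)
    mag = np.abs(coef)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return mag, freqs


def multitaper_spectrum(
    x: np.ndarray,
    fs: float,
    nw: float = 5.0,
    n_tapers: int = 9,
    chunk_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """DPSS multitaper power spectral density averaged over 1-s chunks.

    Non-overlapping chunks, time-bandwidth product 5, nine tapers; the
    one-sided PSD integrates to the signal variance (Parseval).  Returns
    ``(freqs_Hz, psd)``.
    """
    x = np.asarray(x, dtype=float)
    n_chunk = int(round(chunk_s * fs))
    if x.size < n_chunk:
        raise ValueError("need at least one full chunk of signal")
    tapers = signal.windows.dpss(n_chunk, NW=nw, Kmax=n_tapers)  # (K, N), unit energy
    n_chunks = x.size // n_chunk
    freqs = np.fft.rfftfreq(n_chunk, 1.0 / fs)
    psd = np.zeros(freqs.size)
    for k in range(n_chunks):
        seg = x[k * n_chunk:(k + 1) * n_chunk]
        spec = np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2
        psd += spec.mean(axis=0)
    psd /= n_chunks * fs
    psd[1:-1] *= 2  # one-sided
    return freqs, psd


# --------------------------------------------------------------------------- #
# QS oscillatory events

def qs_chunks_before_bouts(
    schedule: StateSchedule, duration_s: float, window_s: float = 1200.0,
    min_len_s: float = 10.0,
) -> list[tuple[float, float]]:
    """QS analysis chunks: up to ``window_s`` preceding each AS bout, with any
    wake intervals removed."""
    wake_ivs = schedule.by_label("wake")
    chunks = []
    for onset in schedule.onsets("AS"):
        s, e = max(onset - window_s, 0.0), onset
        pieces = [(s, e)]
        for ws, we in wake_ivs:
            pieces = [
                p for seg in pieces
                for p in ((seg[0], min(seg[1], ws)), (max(seg[0], we), seg[1]))
                if p[1] - p[0] > 0
            ]
        chunks.extend(p for p in pieces if p[1] - p[0] >= min_len_s)
    return chunks


class OscEvents(NamedTuple):
    times: list                 # per channel: array of event times (s)
    rate_hz: np.ndarray         # per-channel rate, median-filtered across channels
    rate_raw_hz: np.ndarray     # per-channel rate before the channel median filter


def detect_osc_events(
    rec: LFPRecording,
    qs_segments: Sequence[tuple[float, float]],
    params: OscEventParams | None = None,
) -> OscEvents:
    """Detect spindle-like oscillatory events in QS segments, per channel.

    Per channel and segment: 4-40 Hz bandpass, z-score over the segment, peak
    detection with the configured height/prominence/separation.  Rates are
    events/time per segment, averaged over segments with equal weight, then
    median-filtered over a 5-channel window across the channel axis.
    Zero-variance segments contribute no events.
    """
    params = params or OscEventParams()
    if not qs_segments:
        raise ValueError("need at least one QS segment")
    sos = _butter_sos(3, params.band_Hz, "bandpass", rec.fs_Hz)
    dist = max(int(round(params.min_separation_s * rec.fs_Hz)), 1)
    n_ch = rec.n_channels
    times = [[] for _ in range(n_ch)]
    seg_rates = np.zeros((len(qs_segments), n_ch))
    for k, seg in enumerate(qs_segments):
        x = _slice(rec, seg)
        if x.shape[1] < 10:
            continue
        xf = _filtfilt(sos, x.astype(np.float64))
        sd = xf.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # zero-variance segment -> no events
        z = (xf - xf.mean(axis=1, keepdims=True)) / sd
        span = x.shape[1] / rec.fs_Hz
        for c in range(n_ch):
            peaks, _ = signal.find_peaks(
                z[c], height=params.min_height_z,
                prominence=params.min_prominence_z, distance=dist,
            )
            times[c].append(seg[0] + peaks / rec.fs_Hz)
            seg_rates[k, c] = peaks.size / span
    times = [np.concatenate(t) if t else np.array([]) for t in times]
    rate_raw = seg_rates.mean(axis=0)
    rate = median_filter(rate_raw, size=params.median_channels, mode="nearest")
    return OscEvents(times, rate, rate_raw)


def fraction_near_flashes(
    event_times: Sequence[float], flash_times: Sequence[float], window_s: float = 10.0
) -> float:
    """Fraction of events within ``window_s`` (two-sided) of any flash."""
    events = np.asarray(event_times, dtype=float)
    flashes = np.sort(np.asarray(flash_times, dtype=float))
    if events.size == 0:
        raise ValueError("no events")
    if flashes.size == 0:
        return 0.0
    idx = np.searchsorted(flashes, events)
    left = flashes[np.clip(idx - 1, 0, flashes.size - 1)]
    right = flashes[np.clip(idx, 0, flashes.size - 1)]
    near = np.minimum(np.abs(events - left), np.abs(events - right)) <= window_s
    return float(near.mean())


# --------------------------------------------------------------------------- #
# region aggregation

def region_aggregate(
    values: np.ndarray,
    channels: pd.DataFrame,
    min_probes: int = 2,
    valid_regions: Sequence[str] | None = None,
    split_ap: bool = False,
    ap_column: str = "y_um",
    anterior_is_min: bool = True,
) -> pd.DataFrame:
    """Aggregate a per-channel map over atlas regions.

    Returns a table indexed by region with the mean value, channel count and
    probe count; regions sampled by fewer than ``min_probes`` probes are
    excluded.  With ``split_ap`` each region is split at the midpoint
    ``(min + max)/2`` of its anterior-posterior coordinate span into
    ``<region>-anterior`` / ``<region>-posterior`` halves (the probe minimum
    applies to the whole region).  Which coordinate axis is anterior is a
    parameter of the channel table, not hard-coded.
    """
    if "probe" not in channels.columns:
        raise ValueError("channel table needs a 'probe' column for region aggregation")
    df = channels.copy()
    df["value"] = np.asarray(values, dtype=float)
    df = df[df["in_brain"].astype(bool)]
    if valid_regions is not None:
        unknown = set(df["region"]) - set(valid_regions)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
    probe_counts = df.groupby("region")["probe"].nunique()
    keep = probe_counts[probe_counts >= min_probes].index
    df = df[df["region"].isin(keep)]
    if split_ap:
        mid = df.groupby("region")[ap_column].transform(lambda a: (a.min() + a.max()) / 2)
        anterior = df[ap_column] < mid if anterior_is_min else df[ap_column] > mid
        df = df.assign(region=df["region"] + np.where(anterior, "-anterior", "-posterior"))
    out = df.groupby("region").agg(
        mean=("value", "mean"),
        n_channels=("value", "size"),
        n_probes=("probe", "nunique"),
    )
    return out


def intensity_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation between two per-channel intensity maps."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("maps must share a channel set of at least 3 channels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an intensity map")
    return float(stats.pearsonr(a, b).statistic)
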