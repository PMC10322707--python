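"""Behavioural correlates of two-stage sleep from brightness and movement traces.

Detectors operate on the *negated* z-scored signal: the resting skin pattern
is uniformly white, so both active-sleep (AS) bouts and quiet-sleep (QS)
colour flashes are brightness decreases, and darkening excursions become
positive peaks after negation.  All filters are zero-phase
(forward-backward Butterworth) so detected event times are not delayed.
z-scoring makes every detector invariant to affine brightness rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal, stats
import statsmodels.api as sm

from .datatypes import BrightnessTrace, MovementTrace, StateSchedule

__all__ = [
    "FlashDetectParams",
    "BoutDurationParams",
    "CircadianParams",
    "TemperatureModelFit",
    "detect_flashes",
    "detect_bout_starts",
    "flash_duration",
    "estimate_bout_duration",
    "circadian_rate",
    "rayleigh_test",
    "fit_temperature_model",
    "reaction_magnitude",
    "breathing_metrics",
    "flash_rate_profile",
    "compare_paired",
    "compare_groups",
]


# --------------------------------------------------------------------------- #
# parameter blocks

@dataclass
class FlashDetectParams:
    """QS colour-flash detection: 0.005-2 Hz 3-pole bandpass, then peaks on the
    negated z-scored trace with height 2 z, prominence 0.5 z, separation 10 s."""

    band_Hz: tuple = (0.005, 2.0)
    filter_poles: int = 3
    min_height_z: float = 2.0
    min_prominence_z: float = 0.5
    min_separation_s: float = 10.0


@dataclass
class BoutDurationParams:
    """AS bout duration: window −10/+100 s around the bout start, z-score,
    0.1 Hz 2-pole lowpass, longest run below −0.2 z."""

    pre_s: float = 10.0
    post_s: float = 100.0
    lowpass_Hz: float = 0.1
    lowpass_poles: int = 2
    threshold_z: float = 0.2

    def __post_init__(self):
        if self.pre_s <= 0 or self.post_s <= 0 or self.threshold_z <= 0:
            raise ValueError("window lengths and threshold must be positive")


@dataclass
class CircadianParams:
    hist_bin_h: float = 2.0
    rate_bin_h: float = 0.1
    smooth_sd_bins: float = 40.0
    kde_bin_min: float = 5.0

    def __post_init__(self):
        if min(self.hist_bin_h, self.rate_bin_h, self.smooth_sd_bins, self.kde_bin_min) <= 0:
            raise ValueError("all circadian parameters must be positive")


@dataclass
class TemperatureModelFit:
    """OLS of inter-bout interval (min) on water temperature (degC)."""

    slope: float            # minutes per degC
    intercept: float        # minutes
    r2: float
    f_stat: float           # F vs intercept-only model
    p_value: float
    n: int
    slope_se: float

    def __str__(self):
        return (f"interval = {self.intercept:.1f} {self.slope:+.2f} * T  "
                f"(R2={self.r2:.2f}, F={self.f_stat:.0f}, p={self.p_value:.3g}, n={self.n})")


# --------------------------------------------------------------------------- #
# helpers

def _zscore(x: np.ndarray) -> np.ndarray:
    """(x - mean)/SD over the analysed span; all-zeros if zero variance."""
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _butter_sos(poles, cutoff, btype, fs):
    return signal.butter(poles, cutoff, btype=btype, fs=fs, output="sos")


def _filtfilt(sos, x):
    padlen = min(3 * (2 * sos.shape[0] + 1), x.size - 1)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


# --------------------------------------------------------------------------- #
# flash and bout detection

def detect_flashes(trace: BrightnessTrace, params: FlashDetectParams | None = None) -> np.ndarray:
    """Detect QS colour-flash peak times (seconds, ascending).

    The trace is bandpass-filtered (zero-phase), negated and z-scored over the
    analysed span; local maxima satisfying the height / prominence /
    separation constraints are returned.  A zero-variance trace yields no
    detections.  Conflicting peaks closer than the minimum separation are
    resolved by keeping the higher peak.
    """
    params = params or FlashDetectParams()
    lo, hi = params.band_Hz
    if not (0 < lo < hi < trace.fps / 2):
        raise ValueError(f"band {params.band_Hz} infeasible for fps={trace.fps}")
    if trace.duration_s < 2.0 / lo:
        raise ValueError("trace shorter than two periods of the highpass corner")
    sos = _butter_sos(params.filter_poles, (lo, hi), "bandpass", trace.fps)
    z = _zscore(-_filtfilt(sos, trace.values))
    if not z.any():
        return np.array([])
    peaks, _ = signal.find_peaks(
        z,
        height=params.min_height_z,
        prominence=params.min_prominence_z,
        distance=max(int(round(params.min_separation_s * trace.fps)), 1),
    )
    return trace.t0 + peaks / trace.fps


def detect_bout_starts(
    trace: BrightnessTrace,
    lowpass_Hz: float = 0.05,
    threshold_z: float = 3.0,
    min_duration_s: float = 20.0,
) -> np.ndarray:
    """Automatic AS bout-start detector (convenience).

    In the study bout starts were identified manually from the brightness
    trace plus video; this detector thresholds the lowpass-filtered negated
    z-score and returns the start time of every suprathreshold run at least
    ``min_duration_s`` long.  The lowpass corner sits well below the flash
    timescale so QS flashes do not trigger it.
    """
    sos = _butter_sos(3, lowpass_Hz, "lowpass", trace.fps)
    z = _zscore(-_filtfilt(sos, trace.values))
    above = z > threshold_z
    if not above.any():
        return np.array([])
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    keep = (ends - starts) >= min_duration_s * trace.fps
    return trace.t0 + starts[keep] / trace.fps


class FlashDurationResult(NamedTuple):
    duration_s: float
    start_s: float
    end_s: float
    clamped: bool  # True if either side never crossed the 2-z threshold


def flash_duration(
    trace: BrightnessTrace,
    peak_s: float,
    pre_s: float = 500 / 24.0,
    post_s: float = 1000 / 24.0,
    threshold_z: float = 2.0,
) -> FlashDurationResult:
    """Duration of a colour flash around a detected peak.

    A window (default 500 frames before to 1000 frames after the peak, at
    24 fps: 21 s / 42 s) is z-scored and negated; the duration runs from the
    last upward threshold crossing before the peak to the first downward
    crossing after it.  A side without a crossing is clamped to the window
    edge and the result flagged; a sub-threshold event falls back to the full
    window, flagged.
    """
    fps = trace.fps
    i_peak = trace.index_of(peak_s)
    i0 = int(round(i_peak - pre_s * fps))
    i1 = int(round(i_peak + post_s * fps))
    if i0 < 0 or i1 > trace.n_frames:
        raise ValueError("flash window does not fit in trace")
    w = _zscore(-trace.values[i0:i1])
    k = i_peak - i0
    above = w >= threshold_z
    clamped = False
    if not above[k]:
        return FlashDurationResult((i1 - i0) / fps, trace.t0 + i0 / fps,
                                   trace.t0 + i1 / fps, True)
    j0 = k
    while j0 > 0 and above[j0 - 1]:
        j0 -= 1
    j1 = k
    while j1 < above.size - 1 and above[j1 + 1]:
        j1 += 1
    if j0 == 0 or j1 == above.size - 1:
        clamped = True
    start = trace.t0 + (i0 + j0) / fps
    end = trace.t0 + (i0 + j1 + 1) / fps
    return FlashDurationResult(end - start, start, end, clamped)


class BoutDurationResult(NamedTuple):
    duration_s: float
    run_start_s: float
    run_end_s: float
    flagged: bool  # True if no sample fell below the threshold


def estimate_bout_duration(
    trace: BrightnessTrace,
    start_s: float,
    params: BoutDurationParams | None = None,
) -> BoutDurationResult:
    """AS bout duration: longest contiguous darkening run in the start window.

    The window is z-scored and lowpass filtered; the duration is the length
    of the longest contiguous run below ``-threshold_z`` (darkening is
    negative on the raw z-scale).  Returns 0 with a flag when nothing falls
    below the threshold.
    """
    params = params or BoutDurationParams()
    fps = trace.fps
    i0 = int(round((start_s - trace.t0 - params.pre_s) * fps))
    i1 = int(round((start_s - trace.t0 + params.post_s) * fps))
    if i0 < 0 or i1 > trace.n_frames:
        raise ValueError("bout window does not fit in trace")
    w = _zscore(trace.values[i0:i1])
    sos = _butter_sos(params.lowpass_poles, params.lowpass_Hz, "lowpass", fps)
    w = _filtfilt(sos, w)
    below = w < -params.threshold_z
    if not below.any():
        return BoutDurationResult(0.0, start_s, start_s, True)
    # longest run of True
    edges = np.diff(np.r_[0, below.astype(int), 0])
    runs_s = np.flatnonzero(edges == 1)
    runs_e = np.flatnonzero(edges == -1)
    k = int(np.argmax(runs_e - runs_s))
    dur = (runs_e[k] - runs_s[k]) / fps
    return BoutDurationResult(
        dur,
        trace.t0 + (i0 + runs_s[k]) / fps,
        trace.t0 + (i0 + runs_e[k]) / fps,
        False,
    )


# --------------------------------------------------------------------------- #
# circadian structure

class CircadianRateResult(NamedTuple):
    hist_counts: np.ndarray     # events per histogram bin
    hist_edges_h: np.ndarray
    rate_times_h: np.ndarray    # fine-bin centres
    rate_per_h: np.ndarray      # Gaussian-smoothed rate, events/hour
    kde_grid_h: np.ndarray
    kde_density: np.ndarray     # probability density over the recording, 1/hour


def circadian_rate(
    bout_times_s: Sequence[float],
    duration_s: float,
    params: CircadianParams | None = None,
) -> CircadianRateResult:
    """Histogram, smoothed rate and kernel density of bout times.

    The smoothed rate is a 0.1-h binned count convolved with a Gaussian of
    SD ``smooth_sd_bins`` bins (reflective edges), expressed in events/hour;
    its time integral equals the event count.  The KDE uses Silverman's
    bandwidth on times snapped to a 5-min grid.
    """
    params = params or CircadianParams()
    t_h = np.sort(np.asarray(bout_times_s, dtype=float)) / 3600.0
    dur_h = duration_s / 3600.0
    if t_h.size and (t_h[0] < 0 or t_h[-1] > dur_h):
        raise ValueError("event times outside [0, duration]")

    hist_edges = np.arange(0, dur_h + params.hist_bin_h, params.hist_bin_h)
    hist_counts, _ = np.histogram(t_h, bins=hist_edges)

    fine_edges = np.arange(0, dur_h + params.rate_bin_h, params.rate_bin_h)
    fine_counts, _ = np.histogram(t_h, bins=fine_edges)
    centres = 0.5 * (fine_edges[:-1] + fine_edges[1:])
    from scipy.ndimage import gaussian_filter1d

    smoothed = gaussian_filter1d(fine_counts.astype(float), params.smooth_sd_bins,
                                 mode="reflect") / params.rate_bin_h

    kde_bin_h = params.kde_bin_min / 60.0
    grid = np.arange(0, dur_h + kde_bin_h, kde_bin_h)
    if t_h.size < 2 or np.ptp(t_h) == 0:
        density = np.zeros_like(grid)
    else:
        snapped = (np.floor(t_h / kde_bin_h) + 0.5) * kde_bin_h
        kde = stats.gaussian_kde(snapped, bw_method="silverman")
        density = kde(grid)
    return CircadianRateResult(hist_counts, hist_edges, centres, smoothed, grid, density)


class RayleighResult(NamedTuple):
    r_bar: float
    z: float
    p: float


def rayleigh_test(event_times_s: Sequence[float], period_h: float = 24.0) -> RayleighResult:
    """Rayleigh test of circular uniformity of event phases.

    Phases are ``2*pi*(t mod period)/period``; the statistic is
    ``Z = n * R_bar**2`` with ``R_bar`` the mean resultant length, and the
    p-value uses the standard finite-n corrected approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rs^2)) - (1 + 2n))`` with ``Rs = n*R_bar``.
    """
    t = np.asarray(event_times_s, dtype=float)
    n = t.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least two events")
    phases = 2 * np.pi * np.mod(t, period_h * 3600.0) / (period_h * 3600.0)
    c, s = np.cos(phases).mean(), np.sin(phases).mean()
    r_bar = float(np.hypot(c, s))
    z = n * r_bar**2
    rs = n * r_bar
    arg = 1 + 4 * n + 4 * (n**2 - rs**2)
    p = float(np.exp(np.sqrt(max(arg, 0.0)) - (1 + 2 * n)))
    return RayleighResult(r_bar, float(z), min(max(p, np.finfo(float).tiny), 1.0))


def fit_temperature_model(
    intervals_min: Sequence[float], temps_C: Sequence[float]
) -> TemperatureModelFit:
    """OLS of inter-bout interval (minutes) on water temperature (degC).

    Reports slope, intercept, R^2 and the F statistic against the
    intercept-only model with its p-value from F(1, n-2).
    """
    y = np.asarray(intervals_min, dtype=float)
    x = np.asarray(temps_C, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need at least three paired observations")
    if np.unique(x).size < 2:
        raise ValueError("temperature must take at least two distinct values")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TemperatureModelFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n=int(y.size),
        slope_se=float(res.bse[1]),
    )


# --------------------------------------------------------------------------- #
# arousal and breathing

def reaction_magnitude(move: MovementTrace, stim_s: float, fps: float | None = None) -> float:
    """Arousal reaction: mean movement 1 s after stimulation minus 1 s before."""
    fps = fps or move.fps
    w = int(round(fps))
    i = int(round((stim_s - move.t0) * fps))
    if i - w < 0 or i + w > move.values.size:
        raise ValueError("stimulation too close to trace edge for a 1-s window")
    return float(move.values[i:i + w].mean() - move.values[i - w:i].mean())


class BreathingMetrics(NamedTuple):
    rate_bpm: np.ndarray   # instantaneous rate interpolated to frame rate
    mean_bpm: float
    cv: float              # SD/mean of inter-peak intervals


def breathing_metrics(residual: MovementTrace, smooth_frames: int = 10,
                      peak_prominence: float = 0.05) -> BreathingMetrics:
    """Breathing rate and arhythmicity from a residual movement trace.

    The trace is smoothed with a ``smooth_frames`` moving average, z-scored,
    and inhalation peaks detected with the given prominence.  The
    instantaneous rate (60 / inter-peak interval, bpm) is linearly
    interpolated to the video frame rate; CV is SD/mean of the intervals.
    """
    if residual.duration_s < 10:
        raise ValueError("need at least 10 s of data")
    kernel = np.ones(smooth_frames) / smooth_frames
    # reflect-pad so the moving average has no zero-padding edge artifacts
    padded = np.pad(residual.values, smooth_frames, mode="reflect")
    sm_trace = np.convolve(padded, kernel, mode="same")[smooth_frames:-smooth_frames]
    z = _zscore(sm_trace)
    peaks, _ = signal.find_peaks(z, prominence=peak_prominence)
    # peaks inside the smoothing edge region are unreliable
    peaks = peaks[(peaks >= 2 * smooth_frames) & (peaks < z.size - 2 * smooth_frames)]
    if peaks.size < 2:
        raise ValueError("fewer than two breath peaks detected")
    ipi = np.diff(peaks) / residual.fps
    inst = 60.0 / ipi
    t = residual.times()
    rate = np.interp(t, residual.t0 + peaks[1:] / residual.fps, inst)
    mean_ipi = ipi.mean()
    return BreathingMetrics(rate, 60.0 / mean_ipi, float(ipi.std() / mean_ipi))


# --------------------------------------------------------------------------- #
# flash-rate profile over the inter-bout interval

def flash_rate_profile(
    flash_times: Sequence[float],
    bout_schedule: StateSchedule,
    n_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flash rate versus normalised position in the inter-bout interval.

    Each complete interval between consecutive AS bouts (with no intervening
    wake) is rescaled to [0, 1]; flash counts are binned and converted to
    events/min, then averaged over intervals.  Returns
    ``(bin_centres, mean_rate, per_interval_rates)``.
    """
    flash_times = np.asarray(flash_times, dtype=float)
    as_ivs = bout_schedule.by_label("AS")
    wake_ivs = bout_schedule.by_label("wake")
    intervals = []
    for (s0, e0), (s1, e1) in zip(as_ivs, as_ivs[1:]):
        if any(ws < s1 and we > e0 for ws, we in wake_ivs):
            continue
        intervals.append((e0, s1))
    if not intervals:
        raise ValueError("schedule contains no complete inter-bout interval")
    rates = np.zeros((len(intervals), n_bins))
    for k, (s, e) in enumerate(intervals):
        span = e - s
        inside = flash_times[(flash_times >= s) & (flash_times < e)]
        u = (inside - s) / span
        counts, _ = np.histogram(u, bins=n_bins, range=(0, 1))
        rates[k] = counts / (span / n_bins / 60.0)
    centres = (np.arange(n_bins) + 0.5) / n_bins
    return centres, rates.mean(axis=0), rates


# --------------------------------------------------------------------------- #
# routine group comparisons (glue over standard tests)

def compare_paired(a, b):
    """Two-sided Wilcoxon signed-rank test for paired state comparisons."""
    return stats.wilcoxon(a, b)


def compare_groups(a, b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for unpaired groups."""
    return stats.mannwhitneyu(a, b, alternative="two-sided")
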