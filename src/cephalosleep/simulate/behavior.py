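"""Synthetic mean-skin-brightness traces with ground truth.

The generator emulates the statistical structure of long-timescale octopus
sleep recordings: a bright (white-skin) baseline with white frame noise,
rhythmic active-sleep (AS) bouts appearing as sustained brightness drops
roughly every hour, and brief colour flashes during the quiet sleep (QS)
separating bouts, whose rate decays across each inter-bout interval.

Skin darkening is modelled as a brightness *decrease* (the resting pattern is
uniformly white), so all events are negative deflections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from ..datatypes import BrightnessTrace, StateSchedule, SyntheticTruth

__all__ = ["BehaviorSimConfig", "gen_brightness_trace"]

#: reference temperature (degC) at which base_interval_min applies
T_REF_C = 22.0


@dataclass
class BehaviorSimConfig:
    """Parameters of the behavioural-trace generator.

    Defaults follow the descriptive statistics of recorded sleep behaviour:
    ~hourly AS bouts of 75 +/- 28 s at 22 degC, each 1 degC of warming
    shortening the inter-bout interval by ~5 min, and ~7.1-s QS colour
    flashes at a decaying rate.
    """

    duration_h: float = 24.0
    fps: float = 24.0
    temperature_C: float = 22.0
    #: mean inter-bout interval (minutes) at the reference temperature
    base_interval_min: float = 60.0
    #: change in mean interval per degC above reference
    interval_slope_min_per_C: float = -5.0
    #: SD of the inter-bout interval, minutes
    interval_sd_min: float = 16.4
    bout_duration_mean_s: float = 75.0
    bout_duration_sd_s: float = 28.0
    #: bout-rate multiplier during subjective day (>= 1); 1 disables
    #: circadian modulation.  Applied as a two-level day/night multiplier
    #: with a 30-min cosine taper matching the lighting protocol.
    circadian_day_gain: float = 1.0
    #: start of the 12-h subjective day, hours from trace start
    day_start_h: float = 0.0
    flash_duration_s: float = 7.1
    flash_duration_sd_s: float = 0.3
    #: flash rate (events/min) at the start / end of each inter-bout interval
    flash_rate_start: float = 1.0
    flash_rate_end: float = 0.2
    #: minimum spacing between flash peaks, seconds
    flash_min_separation_s: float = 12.0
    #: event amplitudes in units of the baseline noise SD
    flash_depth_z: float = 5.0
    bout_depth_z: float = 8.0
    noise_sd: float = 2.0
    baseline: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not (0 < self.flash_duration_s < self.base_interval_min * 60):
            raise ValueError("flash duration must be positive and shorter than a bout interval")
        if not (self.flash_rate_start >= self.flash_rate_end >= 0):
            raise ValueError("flash rates must satisfy start >= end >= 0")
        if self.circadian_day_gain < 1:
            raise ValueError("circadian_day_gain must be >= 1")

    @property
    def mean_interval_min(self) -> float:
        """Mean inter-bout interval at the configured temperature, minutes."""
        return self.base_interval_min + self.interval_slope_min_per_C * (
            self.temperature_C - T_REF_C
        )


def _day_rate_multiplier(t_s: np.ndarray | float, cfg: BehaviorSimConfig) -> np.ndarray:
    """Circadian bout-rate multiplier at time ``t_s`` (1 at night, gain by day).

    Two-level day/night profile with 30-min raised-cosine tapers at the two
    transitions, repeating every 24 h.
    """
    g = cfg.circadian_day_gain
    if g == 1.0:
        return np.ones_like(np.asarray(t_s, dtype=float))
    taper = 0.5  # hours
    h = (np.asarray(t_s, dtype=float) / 3600.0 - cfg.day_start_h) % 24.0
    m = np.ones_like(h)
    # full day level between tapers
    m = np.where((h >= taper) & (h <= 12.0 - taper), g, m)
    # dawn taper (night -> day) over [0, taper]
    ramp_up = 1 + (g - 1) * 0.5 * (1 - np.cos(np.pi * h / taper))
    m = np.where(h < taper, ramp_up, m)
    # dusk taper (day -> night) over [12 - taper, 12]
    ramp_dn = 1 + (g - 1) * 0.5 * (1 - np.cos(np.pi * (12.0 - h) / taper))
    m = np.where((h > 12.0 - taper) & (h < 12.0), ramp_dn, m)
    return m


def _hann_pulse(n: int) -> np.ndarray:
    """Unit-peak raised-cosine pulse of n samples."""
    u = np.arange(n) / max(n - 1, 1)
    return 0.5 * (1 - np.cos(2 * np.pi * u))


def _plateau_pulse(n: int, edge: int) -> np.ndarray:
    """Unit plateau with raised-cosine edges of ``edge`` samples each."""
    w = np.ones(n)
    edge = min(edge, n // 2)
    if edge > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        w[:edge] = ramp
        w[-edge:] = ramp[::-1]
    return w


def _draw_bouts(cfg: BehaviorSimConfig, rng: np.random.Generator, duration_s: float):
    starts, durations = [], []
    mean_s = cfg.mean_interval_min * 60.0
    sd_s = cfg.interval_sd_min * 60.0
    t = 0.0
    while True:
        interval = max(rng.normal(mean_s, sd_s), 300.0)
        interval /= float(_day_rate_multiplier(t + interval / 2, cfg))
        start = t + interval
        dur = max(rng.normal(cfg.bout_duration_mean_s, cfg.bout_duration_sd_s), 10.0)
        if start + dur + 30.0 > duration_s:
            break
        starts.append(start)
        durations.append(dur)
        t = start + dur
    return np.array(starts), np.array(durations)


def _draw_flashes(cfg: BehaviorSimConfig, rng: np.random.Generator,
                  qs_intervals: list[tuple[float, float]]) -> np.ndarray:
    """Inhomogeneous-Poisson flash peaks with linearly decaying rate per interval."""
    margin = cfg.flash_duration_s + 5.0
    flashes = []
    for s, e in qs_intervals:
        lo, hi = s + margin, e - margin
        if hi <= lo:
            continue
        span = e - s
        lam_max = max(cfg.flash_rate_start, cfg.flash_rate_end) / 60.0
        if lam_max <= 0:
            continue
        # Poisson thinning against the linear rate profile over the interval
        n_cand = rng.poisson(lam_max * (hi - lo))
        cand = np.sort(rng.uniform(lo, hi, n_cand))
        u = (cand - s) / span
        lam = (cfg.flash_rate_start + (cfg.flash_rate_end - cfg.flash_rate_start) * u) / 60.0
        keep = rng.uniform(0, lam_max, n_cand) < lam
        accepted = cand[keep]
        # enforce minimum separation by greedy rejection of later conflicts
        last = -np.inf
        for t in accepted:
            if t - last >= cfg.flash_min_separation_s:
                flashes.append(t)
                last = t
    return np.array(sorted(flashes))


def gen_brightness_trace(cfg: BehaviorSimConfig) -> tuple[BrightnessTrace, SyntheticTruth]:
    """Simulate a mean-skin-brightness trace plus ground truth.

    Returns
    -------
    trace : BrightnessTrace of length ``duration_h * 3600 * fps`` frames.
    truth : SyntheticTruth logging every bout and flash, the AS/QS state
        schedule, and the generating parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    duration_s = cfg.duration_h * 3600.0
    n = int(round(duration_s * cfg.fps))
    values = cfg.baseline + rng.normal(0.0, cfg.noise_sd, n)

    bout_starts, bout_durs = _draw_bouts(cfg, rng, duration_s)
    if bout_starts.size == 0:
        warnings.warn("duration too short to contain one bout; empty truth", stacklevel=2)

    for start, dur in zip(bout_starts, bout_durs):
        i0 = int(round(start * cfg.fps))
        m = int(round(dur * cfg.fps))
        pulse = _plateau_pulse(m, int(round(5.0 * cfg.fps)))
        values[i0:i0 + m] -= cfg.bout_depth_z * cfg.noise_sd * pulse[: max(n - i0, 0)]

    # QS intervals between bouts (plus leading/trailing segments)
    edges = [0.0]
    for s, d in zip(bout_starts, bout_durs):
        edges.extend([s, s + d])
    edges.append(duration_s)
    qs_intervals = [(edges[i], edges[i + 1]) for i in range(0, len(edges) - 1, 2)
                    if edges[i + 1] > edges[i]]

    flash_times = _draw_flashes(cfg, rng, qs_intervals)
    flash_durs = np.clip(
        rng.normal(cfg.flash_duration_s, cfg.flash_duration_sd_s, flash_times.size), 1.0, None
    )
    for t, d in zip(flash_times, flash_durs):
        m = int(round(d * cfg.fps))
        i0 = int(round((t - d / 2) * cfg.fps))
        if i0 < 0 or i0 + m > n:
            continue
        values[i0:i0 + m] -= cfg.flash_depth_z * cfg.noise_sd * _hann_pulse(m)

    intervals = [("AS", s, s + d) for s, d in zip(bout_starts, bout_durs)]
    intervals += [("QS", s, e) for s, e in qs_intervals]
    schedule = StateSchedule(intervals)

    trace = BrightnessTrace(values=values, fps=cfg.fps)
    truth = SyntheticTruth(
        bout_starts_s=bout_starts,
        bout_durations_s=bout_durs,
        flash_times_s=flash_times,
        state_schedule=schedule,
        params=asdict(cfg),
        events={"flash_durations_s": flash_durs},
    )
    return trace, truth
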