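"""Synthetic multi-channel LFP with state-dependent band power and QS spindles.

Each channel is the sum of

* a slow 1/f-shaped component band-limited to 0.1-10 Hz, scaled per sample by
  the state's low-band SD,
* a fast flat-spectrum component band-limited to 20-150 Hz, scaled by the
  state's high-band SD,
* a broadband common-mode artifact added *identically* to every channel
  (including out-of-brain channels), emulating shared recording noise that
  median re-referencing should remove exactly,
* on designated channels, spindle-like bursts during quiet sleep only:
  Hann-windowed sinusoids at uniform-random frequency, with heavy-tailed
  (log-normal) inter-event intervals.

The 1/f slow spectrum matters: the 4-40 Hz spindle-detection band then
contains little background power, which is what makes the fixed 2-z peak
threshold of the detector meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ..datatypes import LFPRecording, StateSchedule, SyntheticTruth

__all__ = ["LFPSimConfig", "gen_lfp", "default_channel_table"]

_DEFAULT_BAND_POWER = {
    # state -> (low-band SD, high-band SD) in microvolts; AS > wake > QS
    "QS": (30.0, 4.0),
    "wake": (60.0, 25.0),
    "AS": (90.0, 45.0),
}

_REGIONS = ("sFL", "VL", "Subv", "Subfr", "Buc", "iFL", "Bas", "Ped")


@dataclass
class LFPSimConfig:
    n_channels: int = 64
    fs_Hz: float = 2500.0
    #: indices of channels located outside the brain (used for re-referencing)
    out_of_brain_channels: tuple = ()
    n_out_of_brain: int = 10
    #: state label -> (low-band SD, high-band SD), microvolts
    state_band_power: dict = field(default_factory=lambda: dict(_DEFAULT_BAND_POWER))
    spindle_freq_Hz: tuple = (12.0, 18.0)
    spindle_duration_s: tuple = (0.3, 1.0)
    #: burst peak amplitude range, microvolts ("large, up to ~700 uV")
    spindle_amplitude_uV: tuple = (300.0, 700.0)
    #: log-normal inter-event-interval parameters (median seconds, log-SD)
    spindle_iei_median_s: float = 6.0
    spindle_iei_sigma: float = 0.8
    #: minimum spacing between burst centres, seconds
    spindle_min_iei_s: float = 1.2
    #: channels carrying spindles; default = first 8 in-brain channels
    spindle_channels: tuple = tuple(range(8))
    common_artifact_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not self.out_of_brain_channels:
            self.out_of_brain_channels = tuple(
                range(self.n_channels - self.n_out_of_brain, self.n_channels)
            )
        if set(self.out_of_brain_channels) & set(self.spindle_channels):
            raise ValueError("out_of_brain_channels must be disjoint from spindle_channels")
        if not self.spindle_duration_s[1] <= 1.0 + 1e-9:
            raise ValueError("spindle duration must not exceed 1 s")
        if max(self.spindle_channels, default=-1) >= self.n_channels:
            raise ValueError("spindle channel index out of range")


def default_channel_table(cfg: LFPSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic toy channel table: 8-channel probes, regions cycled.

    ``y_um`` is the anterior-posterior coordinate (smaller = more anterior).
    """
    n = cfg.n_channels
    probe = np.arange(n) // 8
    within = np.arange(n) % 8
    oob = np.zeros(n, dtype=bool)
    oob[list(cfg.out_of_brain_channels)] = True
    region = np.array(
        [_REGIONS[(p + w // 4) % len(_REGIONS)] for p, w in zip(probe, within)], dtype=object
    )
    region[oob] = "outside"
    x = probe * 200.0 + rng.normal(0, 5, n)
    y = within * 30.0 + (probe % 3) * 80.0 + rng.normal(0, 5, n)
    z = within * 10.0 + 50.0
    return pd.DataFrame(
        {"x_um": x, "y_um": y, "z_um": z, "region": region, "in_brain": ~oob, "probe": probe}
    )


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float,
                one_over_f: bool) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to [lo, hi] Hz via spectral synthesis."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    band = (freqs >= lo) & (freqs <= hi)
    amp[band] = 1.0 / freqs[band] if one_over_f else 1.0
    spec = amp * (rng.standard_normal(amp.size) + 1j * rng.standard_normal(amp.size))
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _state_gain_arrays(schedule: StateSchedule, cfg: LFPSimConfig, n: int, fs: float):
    g_low = np.zeros(n)
    g_high = np.zeros(n)
    for label, s, e in schedule.intervals:
        if label not in cfg.state_band_power:
            raise ValueError(f"no band power configured for state {label!r}")
        lo_sd, hi_sd = cfg.state_band_power[label]
        i0, i1 = int(round(s * fs)), min(int(round(e * fs)), n)
        g_low[i0:i1] = lo_sd
        g_high[i0:i1] = hi_sd
    return g_low, g_high


def _draw_spindles(cfg: LFPSimConfig, rng: np.random.Generator,
                   qs_intervals: list[tuple[float, float]]):
    mu = np.log(cfg.spindle_iei_median_s)
    times, freqs, durs, amps = [], [], [], []
    for s, e in qs_intervals:
        t = s + max(rng.lognormal(mu, cfg.spindle_iei_sigma), cfg.spindle_min_iei_s)
        while t < e - 1.0:
            times.append(t)
            freqs.append(rng.uniform(*cfg.spindle_freq_Hz))
            durs.append(rng.uniform(*cfg.spindle_duration_s))
            amps.append(rng.uniform(*cfg.spindle_amplitude_uV))
            t += max(rng.lognormal(mu, cfg.spindle_iei_sigma), cfg.spindle_min_iei_s)
    return (np.array(times), np.array(freqs), np.array(durs), np.array(amps))


def gen_lfp(cfg: LFPSimConfig, schedule: StateSchedule) -> tuple[LFPRecording, SyntheticTruth]:
    """Simulate an LFP recording over the given state schedule.

    The schedule must cover the full recording without gaps; burst times,
    frequencies, durations and amplitudes are logged in the truth.
    """
    duration_s = schedule.end_s
    gaps = schedule.coverage_gaps(duration_s)
    if gaps:
        g = gaps[0]
        raise ValueError(f"schedule leaves interval [{g[0]:.3f}, {g[1]:.3f}] s uncovered")

    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_Hz
    n = int(round(duration_s * fs))
    g_low, g_high = _state_gain_arrays(schedule, cfg, n, fs)

    common = (cfg.common_artifact_sd *
              _band_noise(rng, n, fs, 0.1, min(150.0, fs / 2 * 0.9), one_over_f=False)
              ).astype(np.float32)

    spindle_times, spindle_freqs, spindle_durs, spindle_amps = _draw_spindles(
        cfg, rng, schedule.by_label("QS")
    )
    spindle_phases = rng.uniform(0, 2 * np.pi, spindle_times.size)
    spindle_wave = np.zeros(n, dtype=np.float32)
    for t, f, d, a, ph in zip(spindle_times, spindle_freqs, spindle_durs,
                              spindle_amps, spindle_phases):
        m = int(round(d * fs))
        i0 = int(round((t - d / 2) * fs))
        if i0 < 0 or i0 + m > n:
            continue
        tau = np.arange(m) / fs
        hann = 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / max(m - 1, 1)))
        spindle_wave[i0:i0 + m] += (a * hann * np.sin(2 * np.pi * f * tau + ph)).astype(np.float32)

    data = np.empty((cfg.n_channels, n), dtype=np.float32)
    spindle_set = set(cfg.spindle_channels)
    for c in range(cfg.n_channels):
        slow = _band_noise(rng, n, fs, 0.1, 10.0, one_over_f=True)
        fast = _band_noise(rng, n, fs, 20.0, min(150.0, fs / 2 * 0.9), one_over_f=False)
        ch = g_low * slow + g_high * fast
        data[c] = ch.astype(np.float32) + common
        if c in spindle_set:
            data[c] += spindle_wave

    table = default_channel_table(cfg, rng)
    rec = LFPRecording(data=data, fs_Hz=fs, channels=table)
    truth = SyntheticTruth(
        state_schedule=schedule,
        params=asdict(cfg),
        events={
            "spindle_times_s": spindle_times,
            "spindle_freqs_Hz": spindle_freqs,
            "spindle_durations_s": spindle_durs,
            "spindle_amplitudes_uV": spindle_amps,
        },
    )
    return rec, truth
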