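"""Synthetic movement-magnitude traces (mean optic-flow magnitude).

The trace is a non-negative sum of a breathing oscillation, state-gated body
movement bursts, impulse responses to mechanical stimulation, and optional
noise.  Ground truth logs breath-peak times and the per-stimulus response
amplitude actually applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..datatypes import MovementTrace, StateSchedule, SyntheticTruth

__all__ = ["MovementSimConfig", "gen_movement_trace"]


@dataclass
class MovementSimConfig:
    duration_s: float = 120.0
    fps: float = 25.0
    breathing_rate_bpm: float = 24.0
    breathing_amplitude: float = 1.0
    #: state label -> body-movement burst rate (events/min)
    burst_rate_per_min: dict = field(default_factory=dict)
    #: state label -> burst peak amplitude
    burst_amplitude: dict = field(default_factory=dict)
    burst_duration_s: float = 2.0
    #: mechanical stimulation times, seconds
    stim_times_s: tuple = ()
    #: state label -> reaction amplitude (sustained for response_duration_s)
    response_amplitude: dict = field(default_factory=dict)
    response_duration_s: float = 1.0
    #: schedule of behavioural states; None means a single 'wake' interval
    schedule: StateSchedule | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        amps = [self.breathing_amplitude, self.noise_sd,
                *self.burst_amplitude.values(), *self.response_amplitude.values()]
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        if not self.fps > 0 or not self.duration_s > 0:
            raise ValueError("fps and duration must be positive")


def gen_movement_trace(cfg: MovementSimConfig) -> tuple[MovementTrace, SyntheticTruth]:
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    schedule = cfg.schedule or StateSchedule([("wake", 0.0, cfg.duration_s)])

    # breathing: non-negative raised cosine, one peak per breath
    f = cfg.breathing_rate_bpm / 60.0
    values = cfg.breathing_amplitude * 0.5 * (1 - np.cos(2 * np.pi * f * t))
    breath_peaks = np.arange(0.5 / f, cfg.duration_s, 1.0 / f) if f > 0 else np.array([])
    breath_peaks = breath_peaks[breath_peaks < cfg.duration_s]

    # state-gated movement bursts (half-sine pulses)
    burst_times, burst_states = [], []
    for label, s, e in schedule.intervals:
        rate = cfg.burst_rate_per_min.get(label, 0.0) / 60.0
        amp = cfg.burst_amplitude.get(label, 0.0)
        if rate <= 0 or amp <= 0:
            continue
        n_b = rng.poisson(rate * (e - s))
        for bt in np.sort(rng.uniform(s, e, n_b)):
            i0 = int(round(bt * cfg.fps))
            m = int(round(cfg.burst_duration_s * cfg.fps))
            seg = np.sin(np.pi * np.arange(min(m, n - i0)) / max(m - 1, 1))
            values[i0:i0 + seg.size] += amp * seg
            burst_times.append(bt)
            burst_states.append(label)

    # stimulation responses: rectangular step of the state's amplitude
    applied = []
    for st in cfg.stim_times_s:
        state = schedule.state_at(st) or "wake"
        amp = cfg.response_amplitude.get(state, 0.0)
        i0 = int(round(st * cfg.fps))
        m = int(round(cfg.response_duration_s * cfg.fps))
        values[i0:i0 + m] += amp
        applied.append(amp)

    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, n)
    values = np.maximum(values, 0.0)

    trace = MovementTrace(values=values, fps=cfg.fps)
    truth = SyntheticTruth(
        state_schedule=schedule,
        params={k: v for k, v in asdict(cfg).items() if k != "schedule"},
        events={
            "breath_peak_times_s": breath_peaks,
            "burst_times_s": np.array(burst_times),
            "burst_states": burst_states,
            "stim_times_s": np.array(cfg.stim_times_s, dtype=float),
            "response_amplitudes": np.array(applied),
        },
    )
    return trace, truth
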