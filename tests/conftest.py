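import numpy as np
import pandas as pd
import pytest

from cephalosleep.datatypes import BrightnessTrace, LFPRecording, StateSchedule


def match_events(detected, truth, tol_s):
    """Greedy one-to-one matching of detected to true event times.

    Returns the number of true positives; each truth event is matched at
    most once, to the closest unmatched detection within ``tol_s``.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for t in detected:
        d = np.abs(truth - t)
        d[used] = np.inf
        j = int(d.argmin()) if truth.size else 0
        if truth.size and d[j] <= tol_s:
            used[j] = True
            tp += 1
    return tp


@pytest.fixture
def noise_trace():
    """10-min flat brightness trace with unit white noise at 24 fps."""
    rng = np.random.default_rng(42)
    return BrightnessTrace(200 + rng.normal(0, 1, int(600 * 24)), fps=24.0)


def make_channel_table(n, n_out=1, region="sFL", probes=None):
    regions = [region] * n if isinstance(region, str) else list(region)
    in_brain = [True] * (n - n_out) + [False] * n_out
    for i in range(n - n_out, n):
        regions[i] = "outside"
    return pd.DataFrame({
        "x_um": np.zeros(n), "y_um": np.arange(n, dtype=float) * 10,
        "z_um": np.zeros(n), "region": regions, "in_brain": in_brain,
        "probe": probes if probes is not None else np.zeros(n, dtype=int),
    })


@pytest.fixture
def tone_recording():
    """Three-channel recording (one out-of-brain) carrying a 5 Hz, 50 uV tone."""
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    data = np.tile(50.0 * np.sin(2 * np.pi * 5 * t), (3, 1))
    return LFPRecording(data, fs, make_channel_table(3))


@pytest.fixture
def simple_schedule():
    return StateSchedule([
        ("QS", 0.0, 300.0), ("AS", 300.0, 360.0),
        ("QS", 360.0, 600.0), ("AS", 600.0, 660.0), ("QS", 660.0, 700.0),
    ])
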