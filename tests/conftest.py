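import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import wormhab as wh

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def piecewise_track(worm_id, segments, t0=0.0, dt=0.1, theta=0.0, x0=0.0, y0=0.0):
    """Track crawling along theta with piecewise-constant signed speed.

    ``segments`` is a list of (duration_s, signed_speed_mm_s); positive
    speed moves toward the head (forward), negative away (backward),
    zero is a pause.
    """
    ts = [t0]
    xs = [x0]
    ys = [y0]
    for dur, v in segments:
        n = int(round(dur / dt))
        for _ in range(n):
            ts.append(ts[-1] + dt)
            xs.append(xs[-1] + v * np.cos(theta) * dt)
            ys.append(ys[-1] + v * np.sin(theta) * dt)
    th = np.full(len(ts), theta)
    return wh.WormTrack(worm_id, np.array(ts), np.array(xs), np.array(ys), th)


@pytest.fixture(scope="session")
def tap_protocol():
    return wh.Protocol.tap_habituation(30)


@pytest.fixture(scope="session")
def clean_params():
    """WT-HAB stripped of nuisance processes, for exact generative checks."""
    return dataclasses.replace(
        wh.make_preset("WT-HAB"),
        spont_reversal_rate_hz=0.0,
        pause_fraction=0.0,
        dropout_rate_hz=0.0,
    )


@pytest.fixture(scope="session")
def small_wt_plate(tap_protocol):
    return wh.simulate_plate(wh.make_preset("WT-HAB"), tap_protocol, 20, seed=11)
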