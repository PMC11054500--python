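import numpy as np
import pytest

from walk6mwt.simulate import DEFAULT_ORIGIN
from walk6mwt.trace import GnssSample, WalkTrace, enu_to_latlon


def make_trace(
    xy,
    t=None,
    acc=5.0,
    alt=40.0,
    steps=True,
    accel_mag=1.2,
    speed=None,
    origin=DEFAULT_ORIGIN,
    **meta,
):
    """Build a WalkTrace from planar ENU points (meters) for tests."""
    xy = np.asarray(xy, dtype=float)
    latlon = enu_to_latlon(xy, origin)
    n = xy.shape[0]
    if t is None:
        t = np.arange(n, dtype=float)
    acc = np.broadcast_to(np.asarray(acc, dtype=float), n)
    step_d = np.concatenate([[0.0], np.linalg.norm(np.diff(xy, axis=0), axis=1)])
    cum_steps = np.cumsum(step_d * 1.8).astype(int)
    samples = [
        GnssSample(
            t=float(t[i]),
            lat=float(latlon[i, 0]),
            lon=float(latlon[i, 1]),
            alt=alt,
            acc=float(acc[i]),
            heading=None,
            speed=speed,
            steps=int(cum_steps[i]) if steps else None,
            accel_mag=accel_mag,
        )
        for i in range(n)
    ]
    return WalkTrace(samples=samples, **meta)


def straight_xy(n, speed=1.3):
    """n points heading north at constant speed, 1 s apart."""
    pts = np.zeros((n, 2))
    pts[:, 1] = speed * np.arange(n)
    return pts


@pytest.fixture
def straight_trace():
    return make_trace(straight_xy(61))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
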