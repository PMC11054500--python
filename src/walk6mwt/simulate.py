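"""Seeded simulator of outdoor walk-test GNSS recordings.

The study taxonomy is emulated through seven path families: "regular"
(straight walking), "stop_and_go" (alternating walking and standing),
"back_and_forth" (20 m legs joined by U-turns), and "circles0".."circles3"
(circular paths of decreasing radius, defaults 15/10/6/3 m). Regular and
stop-and-go walks are labelled conventional; the rest unconventional.

Observed fixes are the true 1 Hz positions plus first-order Gauss-Markov
(exponentially correlated) noise per planar axis. Sharp direction changes
are known to degrade smartphone positioning, so the local noise scale
grows with the true turning rate (``turn_noise_gain``); this is what
makes tight circles harder to measure than straight walks, as observed on
real recordings. Optional artifacts reproduce the failure modes the
exclusion filters target: gross position outliers (teleports), stale
repeated timestamps, and fixes without altitude (non-satellite
positioning), which also carry extra position error.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .trace import (
    CONVENTIONAL_PATH_TYPES,
    GnssSample,
    WalkTrace,
    bearing_deg,
    enu_to_latlon,
)

DEFAULT_ORIGIN = (52.0, 13.0)
DEFAULT_CIRCLE_RADII = {"circles0": 15.0, "circles1": 10.0, "circles2": 6.0, "circles3": 3.0}

STEPS_PER_M = 1.8  # walking cadence, steps per meter
ACCEL_WALKING = 1.2  # m/s^2, mean acceleration magnitude while walking
ACCEL_STANDING = 0.05


@dataclass(frozen=True)
class PathSpec:
    """Geometry and timing of a simulated walk."""

    path_type: str = "regular"
    duration_s: float = 360.0
    walk_speed_mps: float = 1.3
    speed_jitter_sd: float = 0.1
    leg_length_m: float = 20.0
    circle_radius_m: Optional[float] = None  # default per circles type

    def __post_init__(self) -> None:
        if self.path_type not in (
            "regular",
            "stop_and_go",
            "back_and_forth",
            *DEFAULT_CIRCLE_RADII,
        ):
            raise ValueError(f"unknown path_type {self.path_type!r}")
        if not 1 <= self.duration_s <= 3600:
            raise ValueError("duration_s out of range")
        if self.walk_speed_mps <= 0 or self.speed_jitter_sd < 0 or self.leg_length_m <= 0:
            raise ValueError("speeds and leg length must be positive")

    @property
    def label(self) -> str:
        return "conventional" if self.path_type in CONVENTIONAL_PATH_TYPES else "unconventional"

    @property
    def radius(self) -> float:
        if self.circle_radius_m is not None:
            return self.circle_radius_m
        return DEFAULT_CIRCLE_RADII.get(self.path_type, 0.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-noise and artifact model.

    Position noise is first-order Gauss-Markov per axis with standard
    deviation ``position_sd_m`` and correlation time ``correlation_s``.
    ``turn_noise_gain`` scales the local noise with the true turning rate
    (1.5 means the sd is 2.5x at 90 deg/s). ``accuracy_bias_m`` plus a
    positive jitter forms the reported accuracy radius.
    """

    position_sd_m: float = 3.0
    correlation_s: float = 20.0
    turn_noise_gain: float = 1.5
    accuracy_bias_m: float = 4.0
    accuracy_jitter_m: float = 2.0
    heading_noise_deg: float = 8.0
    speed_noise_mps: float = 0.15
    outlier_prob: float = 0.0
    outlier_range_m: tuple[float, float] = (60.0, 150.0)
    stale_prob: float = 0.0
    missing_alt_prob: float = 0.0
    missing_alt_error_m: float = 20.0

    def __post_init__(self) -> None:
        for p in (self.outlier_prob, self.stale_prob, self.missing_alt_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in (self.position_sd_m, self.heading_noise_deg, self.speed_noise_mps):
            if s < 0:
                raise ValueError("noise scales must be >= 0")


#: convenience: a noiseless, artifact-free configuration
NOISELESS = NoiseConfig(
    position_sd_m=0.0,
    turn_noise_gain=0.0,
    accuracy_bias_m=5.0,
    accuracy_jitter_m=0.0,
    heading_noise_deg=0.0,
    speed_noise_mps=0.0,
)

#: a configuration with every artifact class active: occasional gross
#: outliers, stale fixes and non-satellite positions (about 1 % of samples each)
ARTIFACTS = NoiseConfig(outlier_prob=0.01, stale_prob=0.01, missing_alt_prob=0.01)


@dataclass
class SimulatedWalk:
    """A simulated recording with its ground truth."""

    trace: WalkTrace
    true_path: np.ndarray  # (n, 2) ENU meters
    true_distance_m: float
    label: str
    path_type: str


def _walking_mask(spec: PathSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-second walking (True) / standing (False) schedule."""
    if spec.path_type != "stop_and_go":
        return np.ones(n, dtype=bool)
    mask = np.zeros(n, dtype=bool)
    i = 0
    walking = True
    while i < n:
        span = int(rng.integers(30, 61)) if walking else int(rng.integers(15, 31))
        mask[i : i + span] = walking
        i += span
        walking = not walking
    return mask


def _true_path(spec: PathSpec, rng: np.random.Generator) -> np.ndarray:
    """1 Hz true positions (ENU meters) from t=0 to t=duration."""
    n = int(round(spec.duration_s)) + 1
    moving = _walking_mask(spec, rng, n - 1)
    speeds = np.where(
        moving,
        np.maximum(0.0, spec.walk_speed_mps + rng.normal(0.0, spec.speed_jitter_sd, n - 1)),
        0.0,
    )
    pts = np.zeros((n, 2))
    if spec.path_type in ("regular", "stop_and_go"):
        # straight line heading north
        pts[1:, 1] = np.cumsum(speeds)
    elif spec.path_type == "back_and_forth":
        pos = 0.0
        direction = 1.0
        for k in range(1, n):
            step = speeds[k - 1]
            while step > 0:
                room = spec.leg_length_m - pos if direction > 0 else pos
                if step <= room:
                    pos += direction * step
                    step = 0.0
                else:
                    pos += direction * room
                    step -= room
                    direction = -direction
            pts[k, 1] = pos
    else:  # circles
        r = spec.radius
        theta = np.concatenate([[0.0], np.cumsum(speeds / r)])
        pts[:, 0] = r * np.cos(theta) - r
        pts[:, 1] = r * np.sin(theta)
    return pts


def _turn_rates_deg(pts: np.ndarray) -> np.ndarray:
    """Per-sample true turning rate in deg/s (0 at endpoints/standstill)."""
    n = pts.shape[0]
    rates = np.zeros(n)
    v = np.diff(pts, axis=0)
    ang = np.arctan2(v[:, 0], v[:, 1])
    moving = np.linalg.norm(v, axis=1) > 1e-9
    for k in range(1, n - 1):
        if moving[k - 1] and moving[k]:
            d = np.degrees(ang[k] - ang[k - 1])
            rates[k] = abs((d + 180.0) % 360.0 - 180.0)
    return rates


def simulate_walk(
    spec: PathSpec,
    noise: NoiseConfig = NOISELESS,
    seed: int = 0,
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    participant_id: str = "sim",
    t_start: float = 0.0,
) -> SimulatedWalk:
    """Simulate one walk-test recording.

    The reference distance is the arc length of the true 1 Hz polyline,
    standing in for the trundle-wheel measurement of a real test.
    """
    rng = np.random.default_rng(seed)
    pts = _true_path(spec, rng)
    n = pts.shape[0]
    true_dist = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    # exponentially correlated positional noise, scaled by turning rate
    phi = np.exp(-1.0 / noise.correlation_s) if noise.correlation_s > 0 else 0.0
    base_sd = noise.position_sd_m
    turn_scale = 1.0 + noise.turn_noise_gain * _turn_rates_deg(pts) / 90.0
    innov_sd = base_sd * np.sqrt(1.0 - phi * phi)
    eps = np.zeros((n, 2))
    if base_sd > 0:
        eps[0] = rng.normal(0.0, base_sd, 2) * turn_scale[0]
        for k in range(1, n):
            eps[k] = phi * eps[k - 1] + rng.normal(0.0, innov_sd, 2) * turn_scale[k]
    observed = pts + eps

    acc = noise.accuracy_bias_m * turn_scale + np.abs(
        rng.normal(0.0, noise.accuracy_jitter_m + 1e-12, n)
    )
    step_dists = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    true_speed = np.concatenate([[0.0], step_dists])
    steps = np.concatenate([[0.0], np.cumsum(step_dists * STEPS_PER_M)]).astype(int)
    moving = np.concatenate([[False], step_dists > 1e-9])
    accel = np.where(moving, ACCEL_WALKING, ACCEL_STANDING) + np.abs(rng.normal(0, 0.05, n))
    alt = 40.0 + rng.normal(0.0, 0.5, n)

    # artifacts
    is_outlier = rng.random(n) < noise.outlier_prob
    is_stale = rng.random(n) < noise.stale_prob
    missing_alt = rng.random(n) < noise.missing_alt_prob
    is_outlier[0] = is_stale[0] = missing_alt[0] = False
    for k in np.flatnonzero(is_outlier):
        radius = rng.uniform(*noise.outlier_range_m)
        angle = rng.uniform(0, 2 * np.pi)
        observed[k] = pts[k] + radius * np.array([np.cos(angle), np.sin(angle)])
    for k in np.flatnonzero(missing_alt):
        radius = rng.uniform(0.5, 1.0) * noise.missing_alt_error_m
        angle = rng.uniform(0, 2 * np.pi)
        observed[k] = observed[k] + radius * np.array([np.cos(angle), np.sin(angle)])

    latlon = enu_to_latlon(observed, origin)
    samples: list[GnssSample] = []
    for k in range(n):
        t = t_start + float(k)
        lat, lon = latlon[k]
        if is_stale[k] and samples:
            # the system replays the last known location and timestamp
            prev = samples[-1]
            samples.append(replace(prev, steps=int(steps[k])))
            continue
        if k + 1 < n and not np.allclose(pts[k], pts[k + 1]):
            a = tuple(enu_to_latlon(pts[k : k + 1], origin)[0])
            b = tuple(enu_to_latlon(pts[k + 1 : k + 2], origin)[0])
            hdg = (bearing_deg(a, b) + rng.normal(0.0, noise.heading_noise_deg)) % 360.0
        else:
            hdg = None
        samples.append(
            GnssSample(
                t=t,
                lat=float(lat),
                lon=float(lon),
                alt=None if missing_alt[k] else float(alt[k]),
                acc=float(acc[k]),
                heading=hdg,
                speed=float(max(0.0, true_speed[k] + rng.normal(0.0, noise.speed_noise_mps))),
                steps=int(steps[k]),
                accel_mag=float(accel[k]),
            )
        )
    trace = WalkTrace(
        samples=samples,
        participant_id=participant_id,
        path_type=spec.path_type,
        label=spec.label,
        reference_distance_m=true_dist,
    )
    return SimulatedWalk(
        trace=trace,
        true_path=pts,
        true_distance_m=true_dist,
        label=spec.label,
        path_type=spec.path_type,
    )


CONVENTIONAL_TYPES = ("regular", "stop_and_go")
UNCONVENTIONAL_TYPES = ("back_and_forth", "circles0", "circles1", "circles2", "circles3")


def simulate_cohort(
    n_participants: int,
    tests_per_participant: int,
    class_mix: dict[str, float] | None = None,
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    duration_s: float = 360.0,
) -> list[SimulatedWalk]:
    """Simulate a cohort with stable participant ids for grouped CV.

    ``class_mix`` maps "conventional"/"unconventional" to proportions
    summing to 1 (default 50/50). Each participant gets a fixed number of
    tests per class (proportions rounded per participant) with randomized
    path types within the class and a per-participant walking-speed
    offset. Byte-identical across runs with the same seed.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    mix = class_mix or {"conventional": 0.5, "unconventional": 0.5}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    walks: list[SimulatedWalk] = []
    n_conv = int(round(tests_per_participant * mix.get("conventional", 0.0)))
    for p in range(n_participants):
        pid = f"P{p:03d}"
        speed = 1.3 + float(rng.normal(0.0, 0.1))
        types = [str(rng.choice(CONVENTIONAL_TYPES)) for _ in range(n_conv)] + [
            str(rng.choice(UNCONVENTIONAL_TYPES))
            for _ in range(tests_per_participant - n_conv)
        ]
        for j, ptype in enumerate(types):
            spec = PathSpec(
                path_type=ptype, duration_s=duration_s, walk_speed_mps=max(0.6, speed)
            )
            walk_seed = int(rng.integers(0, 2**31 - 1))
            walks.append(
                simulate_walk(spec, noise=noise, seed=walk_seed, participant_id=pid)
            )
    return walks
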