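"""Six walked-distance estimators for GNSS walk traces.

All estimators integrate the distance between consecutive (estimated)
positions. Two are selection-based:

* ``baseline`` — sums great-circle distances between every consecutive fix;
* ``qss`` — quality-based spatial sub-sampling: keeps the best-accuracy
  fix per 5 s window, then sums distances between accepted fixes.

Four are tracking filters run at 1 Hz:

* ``alphabeta`` — steady-state alpha-beta filter with per-step gains from
  the tracking index lambda = sigma_w * T^2 / sigma_n, where sigma_w is
  the sample's reported accuracy radius and sigma_n a fixed smoothing
  constant (default 3);
* ``kalman1d`` — two independent position/velocity Kalman filters, one
  per planar axis, with Q built from fixed position/speed standard
  deviations (6 m, 2 m/s) and scalar R = accuracy^2 per step;
* ``kalman2d`` — one joint filter over (x, y, vx, vy, ax, ay) with a
  constant-acceleration transition;
* ``kalmansmooth`` — forward filter plus fixed-interval (RTS) backward
  smoothing on the state (lat, lon, speed), with the fixed observation
  covariance diag(1e-8 deg^2, 1e-8 deg^2, 1e4 (m/s)^2).

The filters operate in the local east-north frame so that meter-valued
covariances are dimensionally coherent; the smoothing variant keeps
degree-valued coordinates because its fixed observation covariance is
stated in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kalman import KalmanSpec, forward_filter, rts_smooth
from .trace import (
    WalkTrace,
    enu_to_latlon,
    haversine_m,
    latlon_to_enu,
    path_length_m,
    resample_1hz,
)

ALGORITHMS = ("baseline", "qss", "alphabeta", "kalman1d", "kalman2d", "kalmansmooth")


@dataclass
class DistanceResult:
    """Walked-distance estimate with per-step diagnostics."""

    distance_m: float
    n_samples_used: int
    algorithm: str
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # lat, lon

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError("distance cannot be negative")


def _result(algorithm: str, latlon: np.ndarray) -> DistanceResult:
    latlon = np.asarray(latlon, dtype=float)
    if latlon.shape[0] < 2:
        return DistanceResult(0.0, latlon.shape[0], algorithm, latlon)
    return DistanceResult(path_length_m(latlon), latlon.shape[0], algorithm, latlon)


def distance_baseline(trace: WalkTrace) -> DistanceResult:
    """Sum of "as the crow flies" distances between consecutive fixes."""
    if len(trace) < 2:
        return DistanceResult(0.0, len(trace), "baseline")
    return _result("baseline", trace.latlon())


def distance_qss(
    trace: WalkTrace,
    window_s: float = 5.0,
    max_speed_mps: float = 2.0,
) -> DistanceResult:
    """Quality-based spatial sub-sampling on a raw (unresampled) trace.

    Tumbling ``window_s`` windows aligned to the first timestamp each
    contribute their lowest-accuracy-radius fix; candidates are then
    accepted sequentially only if time advances, the implied speed stays
    at or below ``max_speed_mps`` and — when step data exist — the step
    count changed. The algorithm embeds its own rules, so no external
    pre-filtering is expected.
    """
    if len(trace) < 2:
        return DistanceResult(0.0, len(trace), "qss")
    samples = trace.samples
    t0 = samples[0].t
    best: dict[int, int] = {}
    for i, s in enumerate(samples):
        w = int((s.t - t0) // window_s)
        if w not in best or s.acc < samples[best[w]].acc:
            best[w] = i
    candidates = [samples[i] for _, i in sorted(best.items())]

    accepted = [candidates[0]]
    for s in candidates[1:]:
        prev = accepted[-1]
        dt = s.t - prev.t
        if dt <= 0:
            continue
        if haversine_m((prev.lat, prev.lon), (s.lat, s.lon)) / dt > max_speed_mps:
            continue
        if s.steps is not None and prev.steps is not None and s.steps == prev.steps:
            continue
        accepted.append(s)
    latlon = np.array([[s.lat, s.lon] for s in accepted])
    return _result("qss", latlon)


def alpha_beta_gains(lam: float) -> tuple[float, float]:
    """Optimal steady-state alpha-beta gains for tracking index ``lam``.

    r = (4 + lam - sqrt(8 lam + lam^2)) / 4, alpha = 1 - r^2,
    beta = 2 (2 - alpha) - 4 sqrt(1 - alpha). Both gains grow
    monotonically from (0, 0) at lam = 0 towards (1, 2) as lam -> inf.
    """
    if lam < 0:
        raise ValueError("tracking index must be >= 0")
    r = (4.0 + lam - math.sqrt(8.0 * lam + lam * lam)) / 4.0
    alpha = 1.0 - r * r
    beta = 2.0 * (2.0 - alpha) - 4.0 * math.sqrt(max(0.0, 1.0 - alpha))
    return alpha, beta


@dataclass(frozen=True)
class AlphaBetaParams:
    """Alpha-beta configuration: sampling interval T, measurement-noise
    smoothing constant sigma_n, and a floor on the per-sample accuracy
    radius (which plays the role of the process scale sigma_w)."""

    T: float = 1.0
    sigma_n: float = 3.0
    acc_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.T <= 0 or self.sigma_n <= 0:
            raise ValueError("T and sigma_n must be positive")


def distance_alpha_beta(
    trace: WalkTrace, params: AlphaBetaParams | None = None
) -> DistanceResult:
    """Alpha-beta tracking on the planar axes of a filtered, 1 Hz trace.

    Per step k: predict position from the previous velocity, then correct
    position by alpha and velocity by beta using the prediction residual.
    The gains come from lambda_k = acc_k * T^2 / sigma_n, the sample's
    accuracy radius playing the role of the process scale: a large radius
    raises lambda and pushes alpha towards 1 (trust the new fix). Initial
    state is the first fix at zero velocity. With every accuracy at zero
    the gains vanish and the filter never moves; the accuracy floor
    avoids that degeneracy by default.
    """
    p = params or AlphaBetaParams()
    if len(trace) < 2:
        return DistanceResult(0.0, len(trace), "alphabeta")
    latlon = trace.latlon()
    xy = latlon_to_enu(latlon)
    accs = np.array([max(s.acc, p.acc_floor) for s in trace.samples])
    T = p.T
    est = np.zeros_like(xy)
    pos = xy[0].copy()
    vel = np.zeros(2)
    est[0] = pos
    for k in range(1, xy.shape[0]):
        lam = accs[k] * T * T / p.sigma_n
        alpha, beta = alpha_beta_gains(lam)
        pred = pos + T * vel
        resid = xy[k] - pred
        pos = pred + alpha * resid
        vel = vel + beta * resid / T
        est[k] = pos
    return _result("alphabeta", enu_to_latlon(est, (latlon[0, 0], latlon[0, 1])))


def _q_outer(stds: np.ndarray) -> np.ndarray:
    return np.outer(stds, stds)


def distance_kalman_1d(
    trace: WalkTrace,
    std_pos: float = 6.0,
    std_speed: float = 2.0,
    T: float = 1.0,
) -> DistanceResult:
    """Two independent axis filters with state (position, velocity).

    Q is the outer product of (std_pos, std_speed) — [[36, 12], [12, 4]]
    at the defaults — and the scalar measurement variance per step is the
    square of that sample's accuracy radius.
    """
    if len(trace) < 2:
        return DistanceResult(0.0, len(trace), "kalman1d")
    latlon = trace.latlon()
    xy = latlon_to_enu(latlon)
    accs = np.array([s.acc for s in trace.samples])
    spec = KalmanSpec(
        A=np.array([[1.0, T], [0.0, 1.0]]),
        Q=_q_outer(np.array([std_pos, std_speed])),
        H=np.array([[1.0, 0.0]]),
    )
    Rs = (accs**2).reshape(-1, 1, 1)
    est = np.zeros_like(xy)
    P0 = np.diag([accs[0] ** 2, std_speed**2])
    for axis in range(2):
        zs = xy[:, axis].reshape(-1, 1)
        x0 = np.array([xy[0, axis], 0.0])
        xs, _, _, _ = forward_filter(spec, zs, Rs, x0, P0)
        est[:, axis] = xs[:, 0]
    return _result("kalman1d", enu_to_latlon(est, (latlon[0, 0], latlon[0, 1])))


def distance_kalman_2d(
    trace: WalkTrace,
    std_pos: float = 6.0,
    std_speed: float = 2.0,
    std_acc: float = 1.0,
    T: float = 1.0,
) -> DistanceResult:
    """One joint constant-acceleration filter over both planar axes.

    State (x, y, vx, vy, ax, ay); Q extends the 1D outer-product
    construction with an acceleration scale std_acc per axis (no
    cross-axis process correlation); R = diag(acc^2, acc^2) per step.
    """
    if len(trace) < 2:
        return DistanceResult(0.0, len(trace), "kalman2d")
    latlon = trace.latlon()
    xy = latlon_to_enu(latlon)
    accs = np.array([s.acc for s in trace.samples])
    A = np.eye(6)
    A[0, 2] = A[1, 3] = T
    A[2, 4] = A[3, 5] = T
    A[0, 4] = A[1, 5] = 0.5 * T * T
    q_axis = _q_outer(np.array([std_pos, std_speed, std_acc]))
    Q = np.zeros((6, 6))
    for ax in range(2):
        idx = np.array([0 + ax, 2 + ax, 4 + ax])
        Q[np.ix_(idx, idx)] = q_axis
    H = np.zeros((2, 6))
    H[0, 0] = H[1, 1] = 1.0
    spec = KalmanSpec(A=A, Q=Q, H=H)
    Rs = np.zeros((len(accs), 2, 2))
    Rs[:, 0, 0] = accs**2
    Rs[:, 1, 1] = accs**2
    x0 = np.array([xy[0, 0], xy[0, 1], 0.0, 0.0, 0.0, 0.0])
    P0 = np.diag([accs[0] ** 2, accs[0] ** 2, std_speed**2, std_speed**2, std_acc**2, std_acc**2])
    xs, _, _, _ = forward_filter(spec, xy, Rs, x0, P0)
    return _result("kalman2d", enu_to_latlon(xs[:, :2], (latlon[0, 0], latlon[0, 1])))


def distance_kalman_smoothing(
    trace: WalkTrace,
    q_coord_deg: float = 1e-4,
    q_speed: float = 0.1,
    resample: bool = True,
) -> DistanceResult:
    """Forward filter plus RTS backward smoothing on (lat, lon, speed).

    The trace is resampled to 1 Hz internally (missing stretches padded)
    unless already on the grid. Coordinates follow a random walk; the
    observation covariance is fixed at diag(1e-8, 1e-8, 1e4) — positions
    in degrees are trusted, the speed channel essentially ignored. The
    initial state is the first available sample. Distance is the length
    of the smoothed coordinate track.
    """
    if len(trace) < 2:
        return DistanceResult(0.0, len(trace), "kalmansmooth")
    work = resample_1hz(trace) if resample else trace
    if len(work) < 2:
        return DistanceResult(0.0, len(work), "kalmansmooth")
    lat = np.array([s.lat for s in work.samples])
    lon = np.array([s.lon for s in work.samples])
    spd = np.array(
        [s.speed if s.speed is not None else 0.0 for s in work.samples], dtype=float
    )
    zs = np.column_stack([lat, lon, spd])
    spec = KalmanSpec(
        A=np.eye(3),
        Q=np.diag([q_coord_deg**2, q_coord_deg**2, q_speed**2]),
        H=np.eye(3),
    )
    R = np.diag([1e-8, 1e-8, 1e4])
    Rs = np.broadcast_to(R, (zs.shape[0], 3, 3))
    x0 = zs[0]
    P0 = R.copy()
    xs, Ps, xps, Pps = forward_filter(spec, zs, Rs, x0, P0)
    xsm, _ = rts_smooth(spec, xs, Ps, xps, Pps)
    return _result("kalmansmooth", xsm[:, :2])


_DISPATCH = {
    "baseline": distance_baseline,
    "qss": distance_qss,
    "alphabeta": distance_alpha_beta,
    "kalman1d": distance_kalman_1d,
    "kalman2d": distance_kalman_2d,
    "kalmansmooth": distance_kalman_smoothing,
}


def estimate_distance(trace: WalkTrace, algorithm: str) -> DistanceResult:
    """Dispatch to one of the six estimators by name."""
    try:
        fn = _DISPATCH[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}") from None
    return fn(trace)


def preprocess_for(algorithm: str, trace: WalkTrace, thresholds=None) -> WalkTrace:
    """Standard pre-processing for an estimator: exclusion filters for
    all algorithms except QSS (which embeds its own), then 1 Hz
    resampling for the tracking filters (the smoother resamples
    internally)."""
    from .filters import apply_filters

    if algorithm == "qss":
        return trace
    kept = apply_filters(trace, thresholds).kept
    if algorithm in ("alphabeta", "kalman1d", "kalman2d") and len(kept) >= 2:
        kept = resample_1hz(kept)
    return kept
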