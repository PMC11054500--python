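"""Minimal linear Kalman filter and fixed-interval (RTS) smoother.

Time-invariant transition/process model; the measurement covariance may
vary per step. The estimate covariance is symmetrized after every update
for numerical hygiene. Gains use a pseudo-inverse so a zero measurement
covariance (perfectly trusted measurement) is handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KalmanSpec:
    """Matrices of a linear-Gaussian state-space model.

    A: state transition, Q: process covariance, H: observation matrix.
    The control matrix B is fixed to zero for walking traces.
    """

    A: np.ndarray
    Q: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.Q.shape != (n, n) or self.H.shape[1] != n:
            raise ValueError("inconsistent state-space dimensions")


def _sym(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def forward_filter(
    spec: KalmanSpec,
    zs: np.ndarray,
    Rs: np.ndarray,
    x0: np.ndarray,
    P0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the forward recursion.

    Parameters
    ----------
    zs : (n, m) measurements; Rs : (n, m, m) per-step measurement covariances.
    x0, P0 : initial state (already conditioned on the first measurement
        by the caller's convention; zs[0] is *not* re-assimilated).

    Returns
    -------
    xs, Ps : posterior states/covariances (n, k) / (n, k, k), with
    xs[0] = x0; and the predicted priors xps, Pps (used by the smoother).
    """
    zs = np.atleast_2d(np.asarray(zs, dtype=float))
    Rs = np.asarray(Rs, dtype=float)
    n, m = zs.shape
    k = spec.A.shape[0]
    xs = np.zeros((n, k))
    Ps = np.zeros((n, k, k))
    xps = np.zeros((n, k))
    Pps = np.zeros((n, k, k))
    x = np.asarray(x0, dtype=float).reshape(k)
    P = _sym(np.atleast_2d(np.asarray(P0, dtype=float)))
    xs[0], Ps[0] = x, P
    xps[0], Pps[0] = x, P
    A, Q, H = spec.A, spec.Q, spec.H
    for i in range(1, n):
        # time update
        xp = A @ x
        Pp = _sym(A @ P @ A.T + Q)
        # measurement update
        R = np.atleast_2d(Rs[i])
        S = H @ Pp @ H.T + R
        K = Pp @ H.T @ np.linalg.pinv(S)
        x = xp + K @ (zs[i] - H @ xp)
        P = _sym((np.eye(k) - K @ H) @ Pp)
        xps[i], Pps[i] = xp, Pp
        xs[i], Ps[i] = x, P
    return xs, Ps, xps, Pps


def rts_smooth(
    spec: KalmanSpec,
    xs: np.ndarray,
    Ps: np.ndarray,
    xps: np.ndarray,
    Pps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Rauch-Tung-Striebel backward pass over forward-filter output."""
    n, k = xs.shape
    xsm = xs.copy()
    Psm = Ps.copy()
    A = spec.A
    for i in range(n - 2, -1, -1):
        G = Ps[i] @ A.T @ np.linalg.pinv(Pps[i + 1])
        xsm[i] = xs[i] + G @ (xsm[i + 1] - xps[i + 1])
        Psm[i] = _sym(Ps[i] + G @ (Psm[i + 1] - Pps[i + 1]) @ G.T)
    return xsm, Psm
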