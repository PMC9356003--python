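"""Spatiotemporal motor-control metrics in the α-space.

* 2-DoF controllability: mean normalized diagonal component of trajectory
  velocities, evaluated per quadrant of the α-plane.  Diagonal motion (both
  degrees of freedom changing together) scores 1, axis-aligned motion 0.
* Motor control performance: 1 minus half the time-averaged Euclidean
  tracking error to the ideal target of the commanded discrete movement.
* Economy of motion: time-averaged fraction of motor intent lying along the
  targeted axis (trajectory straightness).
* Index of difficulty: log-scaled inverse time constraint, anchored to 0 at
  2.0 s and 1 at 0.5 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoding import AlphaTrace

#: Ideal α-space targets (α_INEV, α_PFDF) of the four discrete movements.
TARGETS = {
    "PF": np.array([0.0, -1.0]),
    "DF": np.array([0.0, 1.0]),
    "IN": np.array([-1.0, 0.0]),
    "EV": np.array([1.0, 0.0]),
}

#: Unit diagonal direction in the α-plane.
DELTA_11 = np.array([1.0, 1.0]) / np.sqrt(2.0)

#: Minimum consecutive in-quadrant samples for a full trajectory.
MIN_TRAJECTORY_SAMPLES = 5

_AXIS_EPS = 1e-6  # samples this close to an axis belong to no quadrant
_SPEED_EPS = 1e-6  # velocity norms below this are treated as rest


@dataclass
class TrajectorySegment:
    quadrant: int
    start: int
    end: int  # end-exclusive sample index


def _quadrant_labels(alpha: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Quadrant (1-4) per sample; 0 for boundary or undefined samples."""
    x, y = alpha[:, 0], alpha[:, 1]
    q = np.zeros(len(x), dtype=int)
    interior = defined & (np.abs(x) >= _AXIS_EPS) & (np.abs(y) >= _AXIS_EPS)
    q[interior & (x > 0) & (y > 0)] = 1
    q[interior & (x < 0) & (y > 0)] = 2
    q[interior & (x < 0) & (y < 0)] = 3
    q[interior & (x > 0) & (y < 0)] = 4
    return q


def segment_quadrant_trajectories(trace: AlphaTrace) -> list[TrajectorySegment]:
    """Maximal runs of >= 5 consecutive samples strictly inside one quadrant."""
    q = _quadrant_labels(trace.alpha, trace.defined)
    segs: list[TrajectorySegment] = []
    start = 0
    for i in range(1, len(q) + 1):
        if i == len(q) or q[i] != q[start]:
            if q[start] != 0 and i - start >= MIN_TRAJECTORY_SAMPLES:
                segs.append(TrajectorySegment(int(q[start]), start, i))
            start = i
    return segs


def alpha_velocity(trace: AlphaTrace) -> np.ndarray:
    """Central-difference velocity of the α trajectory (samples x 2)."""
    dt = np.gradient(trace.time)
    v = np.gradient(trace.alpha, axis=0) / dt[:, None]
    return v


def two_dof_controllability(trace: AlphaTrace) -> float:
    """Mean normalized diagonal velocity component over the four quadrants.

    Per sample, θ = acos(δ11 · |α̇|/||α̇||) ∈ [0, π/4]; θ is time-averaged per
    trajectory, averaged over trajectories per quadrant, normalized by π/4,
    and the four quadrant scores 1 - θ̄/(π/4) are averaged (an empty quadrant
    contributes 0).
    """
    if int(np.sum(trace.defined)) < 2:
        raise ValueError("trace needs at least two defined samples")
    v = alpha_velocity(trace)
    speed = np.linalg.norm(v, axis=1)
    moving = speed > _SPEED_EPS
    if not np.any(moving & trace.defined):
        raise ValueError("no movement in trace; controllability undefined")
    theta = np.full(len(speed), np.nan)
    ok = moving
    theta[ok] = np.arccos(np.clip(DELTA_11 @ (np.abs(v[ok]).T / speed[ok]), -1.0, 1.0))

    per_quadrant: dict[int, list[float]] = {1: [], 2: [], 3: [], 4: []}
    for seg in segment_quadrant_trajectories(trace):
        th = theta[seg.start:seg.end]
        th = th[np.isfinite(th)]
        if th.size:
            per_quadrant[seg.quadrant].append(float(np.mean(th)))
    scores = []
    for j in (1, 2, 3, 4):
        if per_quadrant[j]:
            scores.append(1.0 - float(np.mean(per_quadrant[j])) / (np.pi / 4))
        else:
            scores.append(0.0)
    return float(np.mean(scores))


def motor_control_performance(alpha: np.ndarray, time: np.ndarray, movement: str) -> float:
    """1 - (1/2) x time-averaged Euclidean distance to the movement target."""
    alpha = np.atleast_2d(alpha)
    if alpha.shape[0] == 0:
        raise ValueError("empty trajectory segment")
    target = TARGETS[movement]
    dist = np.linalg.norm(target - alpha, axis=1)
    if len(dist) == 1:
        mean_err = float(dist[0])
    else:
        mean_err = float(np.trapezoid(dist, time) / (time[-1] - time[0]))
    return float(np.clip(1.0 - 0.5 * mean_err, 0.0, 1.0))


def economy_of_motion(alpha: np.ndarray, movement: str) -> float:
    """Time-averaged |α_target-axis| / ||α|| over non-origin samples."""
    alpha = np.atleast_2d(alpha)
    norms = np.linalg.norm(alpha, axis=1)
    keep = norms > 0
    if not np.any(keep):
        raise ValueError("all samples at the origin; economy undefined")
    axis = 1 if movement in ("PF", "DF") else 0
    ratio = np.abs(alpha[keep, axis]) / norms[keep]
    return float(np.mean(ratio))


def index_of_difficulty(time_constraint: float) -> float:
    """ID(T) = ln(2.0/T) / ln(4.0); 0 at T = 2.0 s, 1 at T = 0.5 s."""
    if time_constraint <= 0:
        raise ValueError("time constraint must be positive")
    if not 0.5 <= time_constraint <= 2.0:
        warnings.warn("time constraint outside the calibrated 0.5-2.0 s range; "
                      "index of difficulty extrapolated", stacklevel=2)
    return float(np.log(2.0 / time_constraint) / np.log(4.0))
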