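"""Wall-approach turn detection, CCW/CW labelling and handedness expectations.

A *turn event* opens at the first frame where an agent simultaneously
(1) is within ``wall_distance_max`` of the wall it faces, (2) is farther than
``corner_exclusion`` from every corner, (3) has no other agent inside a
circular sector of radius ``fov_radius`` and half-angle ``fov_half_angle``
about its velocity, and (4) approaches nearly head-on, ``|alpha| <=
alpha_max`` where ``alpha`` is the signed angle between the velocity and the
(outward) wall normal — positive when the velocity points to the right of the
head-on approach direction.  The turn is then labelled from the signed
heading change integrated over ``label_window`` seconds: positive total
rotation = CCW (a left turn).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

from .geometry import Arena, WALL_ORDER
from .geometry import wall_distances as _wall_distances

__all__ = [
    "TurnCriteria",
    "TurnEvent",
    "TurnSummary",
    "detect_turn_events",
    "label_turn",
    "turning_preference_summary",
    "expected_left_turn_fraction",
]

log = logging.getLogger("roamsim")

_OUTWARD = {"E": np.array([1.0, 0.0]), "N": np.array([0.0, 1.0]),
            "W": np.array([-1.0, 0.0]), "S": np.array([0.0, -1.0])}

#: Events with a net heading change below this (radians) are discarded as "no turn".
MIN_TURN_ANGLE = 1e-3
_SPEED_FLOOR = 1e-6


@dataclass(frozen=True)
class TurnCriteria:
    """Eligibility thresholds for a wall-approach turn event."""

    wall_distance_max: float = 2.0
    corner_exclusion: float = 2.0
    fov_radius: float = 2.0
    fov_half_angle: float = 70.0
    alpha_max: float = 10.0
    label_window: float = 2.0

    def __post_init__(self) -> None:
        for name in ("wall_distance_max", "corner_exclusion", "fov_radius",
                     "fov_half_angle", "alpha_max", "label_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fov_half_angle >= 90.0:
            raise ValueError("fov_half_angle must be < 90 degrees")


@dataclass(frozen=True)
class TurnEvent:
    agent_id: int
    t_event: float
    wall_id: str
    alpha: float            # degrees, signed; |alpha| <= alpha_max
    label: str              # "CCW" | "CW"
    heading_change: float   # signed radians over the label window


@dataclass(frozen=True)
class TurnSummary:
    n_total: int
    n_ccw: int
    n_cw: int
    pct_ccw: float | None   # rounded to 0.1 %; None when no events
    pct_cw: float | None
    ci_ccw: tuple[float, float] | None  # exact binomial 95% CI on the CCW fraction


def _signed_alpha_deg(v_hat: np.ndarray, wall_id: str) -> float:
    """Signed angle (deg) between velocity and the outward wall normal.

    Positive when the velocity points to the right of the head-on approach
    (clockwise from the outward normal).
    """
    o = _OUTWARD[wall_id]
    cross = o[0] * v_hat[1] - o[1] * v_hat[0]
    dot = float(o @ v_hat)
    return float(-np.degrees(np.arctan2(cross, dot)))


def _faced_wall(v_hat: np.ndarray) -> str:
    """The wall whose inward normal is most anti-parallel to the velocity."""
    best, best_dot = None, -np.inf
    for w in WALL_ORDER:
        d = float(_OUTWARD[w] @ v_hat)  # outward normal parallel to approach
        if d > best_dot:
            best, best_dot = w, d
    return best


def label_turn(velocities: np.ndarray) -> tuple[str | None, float]:
    """Label a track slice from the signed heading change of its velocities.

    Sums atan2-based angle increments between consecutive velocity directions;
    a positive total means CCW.  Returns ``(label, total_radians)``; the label
    is ``None`` when the net change is below :data:`MIN_TURN_ANGLE`.
    """
    v = np.asarray(velocities, dtype=float)
    speeds = np.hypot(v[:, 0], v[:, 1])
    v = v[speeds > _SPEED_FLOOR]
    if len(v) < 2:
        return None, 0.0
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    dot = v[:-1, 0] * v[1:, 0] + v[:-1, 1] * v[1:, 1]
    total = float(np.arctan2(cross, dot).sum())
    if abs(total) < MIN_TURN_ANGLE:
        return None, total
    return ("CCW" if total > 0 else "CW"), total


def detect_turn_events(traj, arena: Arena | None = None,
                       criteria: TurnCriteria | None = None) -> list[TurnEvent]:
    """Scan a trajectory for eligible wall-approach turns and label them.

    After an event the same agent produces no further event until it has
    retreated beyond ``wall_distance_max + 0.5`` m from the event's wall, so
    one physical approach yields one event.
    """
    arena = arena or Arena()
    criteria = criteria or TurnCriteria()
    if not traj.has_velocities:
        raise ValueError("trajectory has no velocities; run sliding_velocities first")
    times, pos, vel, _, ids = traj.to_arrays()
    nt, n, _ = pos.shape
    corners = arena.corners
    cos_fov = np.cos(np.radians(criteria.fov_half_angle))
    events: list[TurnEvent] = []

    for a in range(n):
        blocked_wall: str | None = None
        for k in range(nt):
            p, v = pos[k, a], vel[k, a]
            dists = _wall_distances(p, arena)
            if blocked_wall is not None:
                if dists[blocked_wall] > criteria.wall_distance_max + 0.5:
                    blocked_wall = None
                else:
                    continue
            speed = float(np.hypot(*v))
            if speed <= _SPEED_FLOOR:
                continue
            v_hat = v / speed
            wall = _faced_wall(v_hat)
            if dists[wall] > criteria.wall_distance_max:          # condition 1
                continue
            if np.min(np.hypot(*(corners - p).T)) <= criteria.corner_exclusion:  # condition 2
                continue
            alpha = _signed_alpha_deg(v_hat, wall)
            if abs(alpha) > criteria.alpha_max:                   # condition 4
                continue
            others = np.delete(np.arange(n), a)
            occupied = False
            for b in others:                                      # condition 3
                d = pos[k, b] - p
                dist = float(np.hypot(*d))
                if dist <= criteria.fov_radius and dist > 0 and (d @ v_hat) / dist >= cos_fov:
                    occupied = True
                    break
            if occupied:
                continue
            # all four conditions hold: label over the window
            t0 = times[k]
            w_mask = (times >= t0) & (times <= t0 + criteria.label_window + 1e-9)
            if times[w_mask][-1] < t0 + criteria.label_window - 1e-9:
                continue  # window extends beyond the track: cannot label
            label, total = label_turn(vel[w_mask, a])
            blocked_wall = wall
            if label is None:
                log.info("discarding no-turn event: agent %s t=%.2f (net %.2g rad)",
                         ids[a], t0, total)
                continue
            events.append(TurnEvent(agent_id=int(ids[a]), t_event=float(t0),
                                    wall_id=wall, alpha=alpha, label=label,
                                    heading_change=total))
    return events


def turning_preference_summary(events, confidence: float = 0.95) -> TurnSummary:
    """Counts, percentages (to 0.1 %) and an exact binomial CI for CCW turns."""
    n_ccw = sum(1 for e in events if e.label == "CCW")
    n_cw = sum(1 for e in events if e.label == "CW")
    n = n_ccw + n_cw
    if n == 0:
        return TurnSummary(0, 0, 0, None, None, None)
    pct_ccw = round(100.0 * n_ccw / n, 1)
    pct_cw = round(100.0 * n_cw / n, 1)
    a = (1.0 - confidence) / 2.0
    lo = 0.0 if n_ccw == 0 else float(beta.ppf(a, n_ccw, n - n_ccw + 1))
    hi = 1.0 if n_ccw == n else float(beta.ppf(1 - a, n_ccw + 1, n - n_ccw))
    return TurnSummary(n, n_ccw, n_cw, pct_ccw, pct_cw, (lo, hi))


def expected_left_turn_fraction(f_right: float, p_left_given_right: float,
                                p_left_given_left: float) -> float:
    """Population left-turn fraction from handedness composition.

    ``f_right * p_left_given_right + (1 - f_right) * p_left_given_left``.
    """
    for name, v in (("f_right", f_right),
                    ("p_left_given_right", p_left_given_right),
                    ("p_left_given_left", p_left_given_left)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return f_right * p_left_given_right + (1.0 - f_right) * p_left_given_left
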