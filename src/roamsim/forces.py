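"""The four force laws acting on each agent, as pure scalar operations.

These reference implementations are deliberately simple (one agent at a
time); the simulation engine uses a compiled vectorized version that is
tested against them.

Force model
-----------
* propulsion: ``mu * (v_d - |v|) * heading`` — velocity relaxation toward the
  desired speed along the current moving direction.
* pair repulsion: long-range exponential (social distancing) beyond contact,
  Hertzian ``eps * overlap^{3/2}`` inside contact (``r_ij <= 2 r0``).
* wall repulsion: same scheme against each wall, plus a dissipative term
  ``-gamma * v_n`` opposing the normal velocity component near the wall.
* turning force: tangential wall force ``A_w2 * exp(...) * cos(alpha)`` along
  ``t_plus`` (CCW-preferring agents) or ``t_minus`` (CW-preferring agents),
  active only while moving toward the wall (``|alpha| < 90 deg``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import Arena, WallFrame, wall_frames

__all__ = ["ModelParams", "AgentState", "propulsion_force", "pair_repulsion",
           "wall_force", "turning_force", "total_force", "SPEED_FLOOR"]

#: Below this speed the heading is held at its previous value (v_hat undefined at v=0).
SPEED_FLOOR = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the model plus switches.

    Defaults are the reference parameter set: ``mu=4``, ``v_d=1.5`` m/s,
    ``r0=0.25`` m, ``A_P=13``, ``B_p=0.85`` m, ``eps=200``, ``A_w1=15``,
    ``A_w2=9``, ``B_w=0.4`` m, unit mass.

    ``damping_range`` bounds the dissipative wall term: the ``-gamma*v_n``
    contribution is applied only while ``r_iw - r0 <= damping_range`` so that
    dissipation stays localized at the boundary.  Set it to ``inf`` for the
    literal unbounded form.

    ``wall_mode`` selects whether the wall and turning forces sum over all
    four walls (``"all_walls"``, default, smooth at corners) or act only from
    the nearest wall (``"nearest_only"``).
    """

    mu: float = 4.0
    v_d: float = 1.5
    r0: float = 0.25
    A_P: float = 13.0
    B_p: float = 0.85
    eps: float = 200.0
    A_w1: float = 15.0
    A_w2: float = 9.0
    B_w: float = 0.4
    gamma: float = 0.0
    mass: float = 1.0
    tp_enabled: bool = False
    tp_ccw_fraction: float = 0.6
    damping_range: float = 1.0
    wall_mode: str = "all_walls"

    def __post_init__(self) -> None:
        positive = {"mu": self.mu, "v_d": self.v_d, "r0": self.r0, "A_P": self.A_P,
                    "B_p": self.B_p, "eps": self.eps, "A_w1": self.A_w1,
                    "A_w2": self.A_w2, "B_w": self.B_w, "mass": self.mass,
                    "damping_range": self.damping_range}
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.tp_ccw_fraction <= 1.0:
            raise ValueError(f"tp_ccw_fraction must be in [0, 1], got {self.tp_ccw_fraction}")
        if self.wall_mode not in ("all_walls", "nearest_only"):
            raise ValueError(f"wall_mode must be 'all_walls' or 'nearest_only', got {self.wall_mode!r}")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class AgentState:
    """Kinematic state of one agent.

    ``heading`` is the unit moving direction, persisted from the last frame
    where the speed exceeded :data:`SPEED_FLOOR`.  ``chirality`` is +1 for a
    CCW (left-turn) preference, -1 for CW, 0 when turning preference is off.
    """

    position: np.ndarray
    velocity: np.ndarray
    heading: np.ndarray | None = None
    chirality: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.heading is None:
            speed = float(np.hypot(*self.velocity))
            if speed <= SPEED_FLOOR:
                raise ValueError("heading must be given explicitly when speed is ~0")
            self.heading = self.velocity / speed
        else:
            self.heading = np.asarray(self.heading, dtype=float)
            norm = float(np.hypot(*self.heading))
            if not np.isclose(norm, 1.0, atol=1e-9):
                raise ValueError(f"heading must be a unit vector, |h| = {norm}")


def propulsion_force(state: AgentState, params: ModelParams) -> np.ndarray:
    """Velocity-relaxation drive ``mu * (v_d - |v|) * heading``."""
    speed = float(np.hypot(*state.velocity))
    return params.mu * (params.v_d - speed) * state.heading


def pair_repulsion(r_i: np.ndarray, r_j: np.ndarray, params: ModelParams) -> np.ndarray:
    """Repulsive force on agent i from agent j.

    Long-range exponential beyond contact distance ``2 r0``, Hertzian contact
    force inside it; direction from j toward i.  The force on j is the exact
    negation (Newton's third law).
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    d = r_i - r_j
    r_ij = float(np.hypot(*d))
    if r_ij == 0.0:
        raise ValueError("coincident agent centres: repulsion direction undefined")
    n_hat = d / r_ij
    contact = 2.0 * params.r0
    if r_ij > contact:
        mag = params.A_P * np.exp(-(r_ij - contact) / params.B_p)
    else:
        mag = params.eps * (1.0 - r_ij / contact) ** 1.5
    return mag * n_hat


def _walls_in_scope(frames: list[WallFrame], params: ModelParams) -> list[WallFrame]:
    if params.wall_mode == "nearest_only":
        return [min(frames, key=lambda f: f.r_iw)]
    return frames


def wall_force(state: AgentState, frames: list[WallFrame], params: ModelParams) -> np.ndarray:
    """Wall repulsion with boundary-localized damping, summed over walls in scope.

    Beyond contact (``r_iw > r0``): ``[A_w1 * exp(-(r_iw - r0)/B_w) - gamma*v_n] n_hat``
    where ``v_n = v . n_hat`` and the damping term is applied only while
    ``r_iw - r0 <= damping_range``.  Inside contact: Hertzian repulsion.
    """
    total = np.zeros(2)
    for f in _walls_in_scope(frames, params):
        if f.r_iw > params.r0:
            mag = params.A_w1 * np.exp(-(f.r_iw - params.r0) / params.B_w)
            if f.r_iw - params.r0 <= params.damping_range:
                v_n = float(state.velocity @ f.n_hat)
                mag -= params.gamma * v_n
        else:
            mag = params.eps * (1.0 - f.r_iw / params.r0) ** 1.5
        total = total + mag * f.n_hat
    return total


def turning_force(state: AgentState, frames: list[WallFrame], params: ModelParams) -> np.ndarray:
    """Tangential turning-preference force, summed over walls in scope.

    ``alpha`` is the angle between the heading and the wall-ward direction
    (``-n_hat``): the force is maximal on a head-on approach (``alpha = 0``),
    decays as ``cos(alpha)``, and is zero when walking parallel to the wall
    or moving away from it (``|alpha| >= 90 deg``).  Acts along ``t_plus``
    for chirality +1 (CCW preference) and ``t_minus`` for -1.
    """
    if not params.tp_enabled:
        raise ValueError("turning_force called with tp_enabled=False")
    if state.chirality not in (1, -1):
        raise ValueError(f"turning_force requires chirality +/-1, got {state.chirality}")
    total = np.zeros(2)
    for f in _walls_in_scope(frames, params):
        cos_alpha = -float(state.heading @ f.n_hat)
        if cos_alpha > 0.0:
            mag = params.A_w2 * np.exp(-(f.r_iw - params.r0) / params.B_w) * cos_alpha
            t_hat = f.t_plus if state.chirality > 0 else f.t_minus
            total = total + mag * t_hat
    return total


def total_force(i: int, states: list[AgentState], arena: Arena, params: ModelParams) -> np.ndarray:
    """Sum of the four force terms on agent ``i``: propulsion + pair repulsion
    over all j != i + wall repulsion + turning force (when enabled)."""
    s = states[i]
    frames = wall_frames(s.position, arena)
    f = propulsion_force(s, params)
    for j, other in enumerate(states):
        if j != i:
            f = f + pair_repulsion(s.position, other.position, params)
    f = f + wall_force(s, frames, params)
    if params.tp_enabled and s.chirality != 0:
        f = f + turning_force(s, frames, params)
    return f
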