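"""Synthetic trajectories with analytically known observables.

These generators produce :class:`~roamsim.simulator.TrajectoryTable` objects
whose ground-truth observables (angular momentum, speeds, turn labels) are
attached under ``meta["ground_truth"]``; they are the cross-module regression
net for the observable and turn-detection code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Arena, EscapedAgentError
from .simulator import TrajectoryTable

__all__ = ["FixtureSpec", "make_fixture"]

KINDS = ("rotating_ring", "radial_burst", "wall_approach", "jittered_static")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic trajectory.

    ``kind`` selects the generator:

    * ``rotating_ring`` — ``n_agents`` equally spaced on a circle of
      ``radius`` rotating at tangential ``speed`` (CCW if ``ccw``);
      ground-truth L = +/- speed.
    * ``radial_burst`` — agents moving radially outward at ``speed``;
      ground-truth L = 0.
    * ``wall_approach`` — a lone agent walking straight at the north wall at
      incidence ``alpha_deg``, then turning 90 deg left (``ccw=True``) or
      right over the label window; exactly one detectable turn event.
    * ``jittered_static`` — static agents with uniform position jitter of
      amplitude ``jitter`` per frame; ground-truth velocity 0.
    """

    kind: str = "rotating_ring"
    n_agents: int = 4
    radius: float = 2.0
    speed: float = 1.0
    ccw: bool = True
    alpha_deg: float = 0.0
    jitter: float = 0.0
    fps: float = 10.0
    duration: float = 10.0
    seed: int = 0
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.fps <= 0 or self.duration <= 0 or self.speed < 0:
            raise ValueError("fps and duration must be positive, speed non-negative")


def _check_inside(pos: np.ndarray, arena: Arena) -> None:
    if not arena.contains(pos.reshape(-1, 2), strict=True).all():
        raise EscapedAgentError("fixture kinematics leave the arena; shrink radius/speed/duration")


def _table(spec: FixtureSpec, times, pos, vel, truth: dict) -> TrajectoryTable:
    _check_inside(pos, spec.arena)
    chi = np.zeros(pos.shape[1], dtype=int)
    meta = {"fixture": spec.kind, "fps": spec.fps, "seed": spec.seed,
            "arena": {"width": spec.arena.width, "height": spec.arena.height},
            "ground_truth": truth}
    return TrajectoryTable.from_arrays(times, pos, vel, chi, meta)


def make_fixture(spec: FixtureSpec) -> TrajectoryTable:
    """Generate the synthetic trajectory described by ``spec``."""
    dt = 1.0 / spec.fps
    times = np.arange(0.0, spec.duration + dt / 2, dt)
    nt = len(times)

    if spec.kind == "rotating_ring":
        sense = 1.0 if spec.ccw else -1.0
        omega = sense * spec.speed / spec.radius
        phases = 2.0 * np.pi * np.arange(spec.n_agents) / spec.n_agents
        ang = omega * times[:, None] + phases[None, :]
        pos = spec.radius * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        vel = spec.speed * sense * np.stack([-np.sin(ang), np.cos(ang)], axis=-1)
        truth = {"L": sense * spec.speed, "speed": spec.speed}
        return _table(spec, times, pos, vel, truth)

    if spec.kind == "radial_burst":
        phases = 2.0 * np.pi * np.arange(spec.n_agents) / spec.n_agents + 0.1
        u = np.stack([np.cos(phases), np.sin(phases)], axis=-1)      # (n, 2)
        r = spec.radius + spec.speed * times                         # (nt,)
        pos = r[:, None, None] * u[None, :, :]
        vel = np.broadcast_to(spec.speed * u, (nt, spec.n_agents, 2)).copy()
        truth = {"L": 0.0, "speed": spec.speed}
        return _table(spec, times, pos, vel, truth)

    if spec.kind == "wall_approach":
        # straight run at the north wall from 4.5 m out, a quarter-circle turn
        # starting 1.5 m from the wall, then straight parallel to the wall
        a = np.radians(spec.alpha_deg)
        # alpha > 0 = velocity to the right of the head-on (+y) approach
        d_hat = np.array([np.sin(a), np.cos(a)])
        t_turn = 2.0                   # quarter-turn duration (the label window)
        approach_time = 3.0 / spec.speed   # 3 m of straight approach
        if spec.duration < approach_time + t_turn:
            raise ValueError("duration too short for the wall_approach fixture")
        sense = 1.0 if spec.ccw else -1.0
        omega = sense * (np.pi / 2) / t_turn
        rad = spec.speed / abs(omega)
        # worst-case wall-ward advance of the arc (geometry is independent of
        # where the turn starts); keep a 0.3 m clearance beyond it
        centre0 = rad * sense * np.array([-d_hat[1], d_hat[0]])
        th0 = np.arctan2(-centre0[1], -centre0[0])
        th_samples = th0 + omega * t_turn * np.linspace(0.0, 1.0, 201)
        advance = float(np.max(centre0[1] + rad * np.sin(th_samples)))
        turn_start_dist = max(advance, 0.0) + 0.3
        p_turn = np.array([0.0, spec.arena.half_height - turn_start_dist])
        p0 = p_turn - spec.speed * approach_time * d_hat
        centre = p_turn + rad * sense * np.array([-d_hat[1], d_hat[0]])
        theta0 = np.arctan2(p_turn[1] - centre[1], p_turn[0] - centre[0])
        th_end = theta0 + omega * t_turn
        p_end = centre + rad * np.array([np.cos(th_end), np.sin(th_end)])
        v_end = spec.speed * sense * np.array([-np.sin(th_end), np.cos(th_end)])
        # post-turn straight run stops 0.7 m before hitting any wall
        t_stop = np.inf
        for c in range(2):
            lim = (spec.arena.half_width, spec.arena.half_height)[c] - 0.7
            if v_end[c] > 1e-12:
                t_stop = min(t_stop, (lim - p_end[c]) / v_end[c])
            elif v_end[c] < -1e-12:
                t_stop = min(t_stop, (-lim - p_end[c]) / v_end[c])
        t_stop = max(t_stop, 0.0)
        pos = np.empty((nt, 1, 2))
        vel = np.empty((nt, 1, 2))
        for k, t in enumerate(times):
            if t <= approach_time:
                pos[k, 0] = p0 + spec.speed * t * d_hat
                vel[k, 0] = spec.speed * d_hat
            elif t <= approach_time + t_turn:
                th = theta0 + omega * (t - approach_time)
                pos[k, 0] = centre + rad * np.array([np.cos(th), np.sin(th)])
                vel[k, 0] = spec.speed * sense * np.array([-np.sin(th), np.cos(th)])
            else:
                s = t - approach_time - t_turn
                if s <= t_stop:
                    pos[k, 0] = p_end + v_end * s
                    vel[k, 0] = v_end
                else:
                    pos[k, 0] = p_end + v_end * t_stop
                    vel[k, 0] = 0.0
        truth = {"label": "CCW" if spec.ccw else "CW", "alpha_deg": spec.alpha_deg,
                 "wall_id": "N", "n_events": 1, "speed": spec.speed}
        return _table(spec, times, pos, vel, truth)

    # jittered_static
    rng = np.random.default_rng(spec.seed)
    phases = 2.0 * np.pi * np.arange(spec.n_agents) / spec.n_agents
    base = spec.radius * np.stack([np.cos(phases), np.sin(phases)], axis=-1)
    jit = rng.uniform(-spec.jitter, spec.jitter, size=(nt, spec.n_agents, 2))
    pos = base[None, :, :] + jit
    vel = np.zeros_like(pos)
    truth = {"L": 0.0, "speed": 0.0, "jitter": spec.jitter}
    return _table(spec, times, pos, vel, truth)


def mirror_pair(spec: FixtureSpec) -> tuple[TrajectoryTable, TrajectoryTable]:
    """A fixture and its reflection about the x-axis; their L series are exact
    negations of each other."""
    t = make_fixture(spec)
    return t, t.mirrored()
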