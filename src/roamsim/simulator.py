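"""Forward-Euler simulation runs and the recorded trajectory container."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .engine import integrate
from .forces import SPEED_FLOOR, ModelParams
from .geometry import Arena, EscapedAgentError

__all__ = ["SimConfig", "States", "TrajectoryTable", "initialize", "step", "run"]

log = logging.getLogger("roamsim")

TRAJ_COLUMNS = ["t", "agent_id", "x", "y", "vx", "vy", "chirality"]


@dataclass(frozen=True)
class SimConfig:
    """Run protocol: size, duration, burn-in, time step, recording cadence."""

    n_agents: int = 24
    duration: float = 1000.0
    burn_in: float = 200.0
    dt: float = 0.01
    record_interval: float = 0.1
    seed: int = 0
    initial_min_separation: float = 1.0
    initial_speed: float | None = None  # None -> params.v_d

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.record_interval < self.dt:
            raise ValueError("record_interval must be >= dt")
        if not self.burn_in < self.duration:
            raise ValueError("burn_in must be smaller than duration")
        ratio = self.record_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("record_interval must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def record_every(self) -> int:
        return int(round(self.record_interval / self.dt))

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class States:
    """Array-of-structs state for all agents."""

    positions: np.ndarray   # (n, 2)
    velocities: np.ndarray  # (n, 2)
    headings: np.ndarray    # (n, 2), unit vectors
    chiralities: np.ndarray  # (n,), values in {+1, -1, 0}

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "States":
        return States(self.positions.copy(), self.velocities.copy(),
                      self.headings.copy(), self.chiralities.copy())


@dataclass
class TrajectoryTable:
    """Recorded trajectory: long-format frame plus run metadata.

    Columns: ``t, agent_id, x, y, vx, vy, chirality``; every recorded time has
    exactly ``n_agents`` rows and all positions are strictly inside the arena.
    """

    frame: pd.DataFrame
    meta: dict

    @property
    def n_agents(self) -> int:
        return int(self.frame["agent_id"].nunique())

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.frame["t"].to_numpy())

    @property
    def has_velocities(self) -> bool:
        return "vx" in self.frame.columns and not self.frame["vx"].isna().all()

    def to_arrays(self):
        """Return ``(times, pos, vel, chirality, agent_ids)`` with ``pos`` and
        ``vel`` of shape ``(n_times, n_agents, 2)``.

        Requires a complete rectangular table (same agents at every time).
        """
        df = self.frame.sort_values(["t", "agent_id"], kind="mergesort")
        times = np.unique(df["t"].to_numpy())
        ids = np.unique(df["agent_id"].to_numpy())
        nt, n = len(times), len(ids)
        if len(df) != nt * n:
            raise ValueError("trajectory is not rectangular (missing agent/time rows)")
        pos = df[["x", "y"]].to_numpy().reshape(nt, n, 2)
        if self.has_velocities:
            vel = df[["vx", "vy"]].to_numpy().reshape(nt, n, 2)
        else:
            vel = np.full((nt, n, 2), np.nan)
        chi = df["chirality"].to_numpy().reshape(nt, n)[0].astype(int)
        return times, pos, vel, chi, ids

    @classmethod
    def from_arrays(cls, times, pos, vel, chiralities, meta=None) -> "TrajectoryTable":
        nt, n, _ = pos.shape
        df = pd.DataFrame({
            "t": np.repeat(times, n),
            "agent_id": np.tile(np.arange(n), nt),
            "x": pos[:, :, 0].ravel(),
            "y": pos[:, :, 1].ravel(),
            "vx": vel[:, :, 0].ravel(),
            "vy": vel[:, :, 1].ravel(),
            "chirality": np.tile(np.asarray(chiralities, dtype=int), nt),
        })
        return cls(frame=df, meta=dict(meta or {}))

    def mirrored(self) -> "TrajectoryTable":
        """Reflection about the x-axis: y, vy negated and chirality flipped."""
        df = self.frame.copy()
        df["y"] = -df["y"]
        df["vy"] = -df["vy"]
        df["chirality"] = -df["chirality"]
        meta = dict(self.meta)
        meta["mirrored"] = not meta.get("mirrored", False)
        return TrajectoryTable(frame=df, meta=meta)


def initialize(config: SimConfig, params: ModelParams, rng: np.random.Generator,
               arena: Arena | None = None, max_attempts: int = 100_000) -> States:
    """Draw the initial agent states.

    Positions are rejection-sampled uniformly with pairwise distance at least
    ``initial_min_separation`` and wall clearance at least ``r0 + 0.1`` m;
    headings are uniform on the circle; every agent starts at
    ``initial_speed`` (default ``v_d``).  With turning preference enabled,
    ``round(tp_ccw_fraction * n)`` agents (shuffled) get chirality +1 and the
    rest -1.
    """
    arena = arena or Arena()
    n = config.n_agents
    clearance = params.r0 + 0.1
    lo = np.array([-arena.half_width + clearance, -arena.half_height + clearance])
    hi = np.array([arena.half_width - clearance, arena.half_height - clearance])
    if np.any(hi <= lo):
        raise ValueError("arena too small for the requested wall clearance")

    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} agents with min separation "
                f"{config.initial_min_separation} m after {max_attempts} attempts")
        attempts += 1
        cand = lo + rng.random(2) * (hi - lo)
        if all(np.hypot(*(cand - p)) >= config.initial_min_separation for p in placed):
            placed.append(cand)
    positions = np.array(placed)

    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    headings = np.column_stack([np.cos(angles), np.sin(angles)])
    speed = params.v_d if config.initial_speed is None else config.initial_speed
    velocities = speed * headings
    if speed <= SPEED_FLOOR and config.initial_speed is not None:
        velocities = np.zeros_like(headings)

    chiralities = np.zeros(n, dtype=int)
    if params.tp_enabled:
        n_ccw = int(np.rint(params.tp_ccw_fraction * n))
        perm = rng.permutation(n)
        chiralities[perm[:n_ccw]] = 1
        chiralities[perm[n_ccw:]] = -1
    return States(positions, velocities, headings, chiralities)


def step(states: States, arena: Arena, params: ModelParams, dt: float,
         t: float = 0.0) -> States:
    """One forward-Euler step: ``x += dt*v`` (old velocity), ``v += dt*F/m``.

    Raises :class:`EscapedAgentError` if an agent leaves the arena.
    """
    rec_pos, rec_vel, esc_agent, esc_step = integrate(
        states.positions, states.velocities, states.headings,
        states.chiralities, arena, params, dt, n_steps=1, record_every=1)
    if esc_agent >= 0:
        raise EscapedAgentError(
            f"agent {esc_agent} escaped the arena at t = {t + dt:.4f} s "
            "(time step too large?)", agent_id=esc_agent, time=t + dt)
    new_pos, new_vel = rec_pos[1], rec_vel[1]
    speeds = np.hypot(new_vel[:, 0], new_vel[:, 1])
    new_head = states.headings.copy()
    moving = speeds > SPEED_FLOOR
    new_head[moving] = new_vel[moving] / speeds[moving, None]
    return States(new_pos, new_vel, new_head, states.chiralities.copy())


def run(config: SimConfig, params: ModelParams, arena: Arena | None = None,
        initial: States | None = None) -> TrajectoryTable:
    """Simulate ``config.duration`` seconds and record every ``record_interval``.

    Fully reproducible from ``(config.seed, config, params)``; an explicit
    ``initial`` state overrides the seeded initialization (used for mirror
    tests).
    """
    arena = arena or Arena()
    rng = np.random.default_rng(config.seed)
    states = initial.copy() if initial is not None else initialize(config, params, rng, arena)
    log.info("run: n=%d gamma=%.3g tp=%s seed=%d duration=%gs",
             config.n_agents, params.gamma, params.tp_enabled, config.seed,
             config.duration)
    rec_pos, rec_vel, esc_agent, esc_step = integrate(
        states.positions, states.velocities, states.headings,
        states.chiralities, arena, params,
        config.dt, config.n_steps, config.record_every)
    if esc_agent >= 0:
        t_esc = (esc_step + 1) * config.dt
        raise EscapedAgentError(
            f"agent {esc_agent} escaped the arena at t = {t_esc:.4f} s "
            "(time step too large?)", agent_id=esc_agent, time=t_esc)
    times = np.arange(rec_pos.shape[0]) * config.record_interval
    meta = {
        "params": params.to_dict(),
        "config": config.to_dict(),
        "seed": config.seed,
        "arena": {"width": arena.width, "height": arena.height},
    }
    return TrajectoryTable.from_arrays(times, rec_pos, rec_vel,
                                       states.chiralities, meta)
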