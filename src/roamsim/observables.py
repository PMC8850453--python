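"""Order parameter, coarse-grained fields, Voronoi areas, velocity estimates.

The vortex order parameter is the normalized angular momentum

    L(t) = (1/N) * sum_i (r_i x v_i)_z / |r_i|

about the arena centre: positive for counterclockwise rotation, in speed
units (m/s), with every agent contributing equally regardless of its distance
to the centre.  An unnormalized variant (no division by |r_i|) is provided
for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Arena

__all__ = [
    "LSeries",
    "FieldGrid",
    "angular_momentum",
    "l_series",
    "time_avg_L",
    "coarse_grain_fields",
    "voronoi_areas",
    "sliding_velocities",
]


@dataclass
class LSeries:
    """Scalar angular-momentum time series in speed units (m/s)."""

    times: np.ndarray
    values: np.ndarray
    n_agents: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")


def angular_momentum(positions: np.ndarray, velocities: np.ndarray,
                     center=(0.0, 0.0), normalized: bool = True) -> float:
    """Normalized angular momentum of one frame; positive = CCW.

    ``normalized=False`` drops the per-agent 1/|r_i| factor (robustness
    variant; units then m^2/s).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float)) - np.asarray(center, dtype=float)
    vel = np.atleast_2d(np.asarray(velocities, dtype=float))
    if pos.shape[0] < 1:
        raise ValueError("need at least one agent")
    cross_z = pos[:, 0] * vel[:, 1] - pos[:, 1] * vel[:, 0]
    if normalized:
        r = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(r == 0.0):
            raise ValueError("agent exactly at the centre: 1/|r| undefined")
        cross_z = cross_z / r
    return float(cross_z.mean())


def l_series(traj, center=(0.0, 0.0), normalized: bool = True) -> LSeries:
    """Per-frame angular momentum of a trajectory table."""
    times, pos, vel, _, _ = traj.to_arrays()
    if np.isnan(vel).any():
        raise ValueError("trajectory has no velocities; run sliding_velocities first")
    values = np.empty(len(times))
    for k in range(len(times)):
        values[k] = angular_momentum(pos[k], vel[k], center, normalized)
    return LSeries(times=times, values=values, n_agents=pos.shape[1])


def time_avg_L(series: LSeries, burn_in: float) -> float:
    """Arithmetic mean of L(t) over frames with t > burn_in."""
    mask = series.times > burn_in
    if not mask.any():
        raise ValueError(f"no frames after burn-in t > {burn_in}")
    return float(series.values[mask].mean())


@dataclass
class FieldGrid:
    """Time-averaged coarse-grained fields on a regular grid.

    ``density`` is persons/m^2, ``speed`` the time average of the local speed
    field |v(r, t)|, ``velocity`` the mean velocity vector (for arrow plots).
    Cells never covered by any agent disc have NaN speed/velocity.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    density: np.ndarray          # (ny, nx)
    speed: np.ndarray            # (ny, nx)
    velocity: np.ndarray         # (ny, nx, 2)
    omega: float
    grid_spacing: float

    def density_integral(self) -> float:
        """Quadrature integral of the density field over the grid."""
        return float(self.density.sum() * self.grid_spacing ** 2)


def _kernel_masks(pos_frame, xs, ys, omega):
    """Boolean disc masks (ny, nx) for each agent in one frame."""
    dx = xs[None, None, :] - pos_frame[:, 0, None, None]
    dy = ys[None, :, None] - pos_frame[:, 1, None, None]
    return dx * dx + dy * dy <= omega * omega


def coarse_grain_fields(traj, omega: float = 0.25, grid_spacing: float = 0.1,
                        burn_in: float = 0.0, arena: Arena | None = None) -> FieldGrid:
    """Disc-kernel ("Heaviside") coarse-grained density and velocity fields.

    Each agent spreads a weight 1/(pi omega^2) uniformly over a disc of radius
    ``omega``; instantaneous density and momentum fields are formed per frame
    and the time averages are taken over frames with t > burn_in (t >= 0 when
    burn_in is 0).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    arena = arena or Arena()
    times, pos, vel, _, _ = traj.to_arrays()
    mask = times > burn_in if burn_in > 0 else np.ones(len(times), dtype=bool)
    if not mask.any():
        raise ValueError("no frames after burn-in")
    have_vel = not np.isnan(vel).any()

    xs = np.arange(-arena.half_width + grid_spacing / 2, arena.half_width, grid_spacing)
    ys = np.arange(-arena.half_height + grid_spacing / 2, arena.half_height, grid_spacing)
    w = 1.0 / (np.pi * omega ** 2)

    dens_sum = np.zeros((len(ys), len(xs)))
    speed_sum = np.zeros_like(dens_sum)
    vel_sum = np.zeros((len(ys), len(xs), 2))
    covered = np.zeros_like(dens_sum)  # frames where the local velocity is defined
    n_frames = 0
    for k in np.flatnonzero(mask):
        discs = _kernel_masks(pos[k], xs, ys, omega).astype(float)  # (n, ny, nx)
        rho = w * discs.sum(axis=0)
        dens_sum += rho
        n_frames += 1
        if have_vel:
            mom = w * np.einsum("nij,nc->ijc", discs, vel[k])
            occ = rho > 0
            v_loc = np.zeros_like(mom)
            v_loc[occ] = mom[occ] / rho[occ, None]
            speed_sum[occ] += np.hypot(v_loc[occ, 0], v_loc[occ, 1])
            vel_sum[occ] += v_loc[occ]
            covered += occ

    density = dens_sum / n_frames
    speed = np.full_like(density, np.nan)
    velocity = np.full_like(vel_sum, np.nan)
    if have_vel:
        seen = covered > 0
        speed[seen] = speed_sum[seen] / covered[seen]
        velocity[seen] = vel_sum[seen] / covered[seen, None]
    return FieldGrid(x_centers=xs, y_centers=ys, density=density, speed=speed,
                     velocity=velocity, omega=omega, grid_spacing=grid_spacing)


def _clip_halfplane(poly: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex polygon to {x : a.x <= b}."""
    out = []
    m = len(poly)
    for k in range(m):
        p, q = poly[k], poly[(k + 1) % m]
        fp, fq = a @ p - b, a @ q - b
        if fp <= 0:
            out.append(p)
        if (fp < 0 < fq) or (fq < 0 < fp):
            t = fp / (fp - fq)
            out.append(p + t * (q - p))
    return np.array(out) if out else np.empty((0, 2))


def _polygon_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_areas(positions: np.ndarray, arena: Arena | None = None) -> np.ndarray:
    """Area of each agent's Voronoi cell clipped to the arena rectangle.

    Cells are built by intersecting the rectangle with the perpendicular-
    bisector half-planes against every other agent — exact for rectangles and
    bounded by construction.  The areas always partition the arena area.
    """
    arena = arena or Arena()
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pos)
    if n >= 2:
        from scipy.spatial.distance import pdist
        if pdist(pos).min() == 0.0:
            raise ValueError("duplicate positions: Voronoi cell undefined")
    hw, hh = arena.half_width, arena.half_height
    rect = np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]])
    areas = np.empty(n)
    for i in range(n):
        poly = rect
        for j in range(n):
            if j == i or len(poly) == 0:
                continue
            # keep points closer to i than to j: (x - mid) . (pj - pi) <= 0
            d = pos[j] - pos[i]
            mid = 0.5 * (pos[i] + pos[j])
            poly = _clip_halfplane(poly, d, float(d @ mid))
        areas[i] = _polygon_area(poly)
    return areas


def sliding_velocities(traj, window: float = 0.76):
    """Velocity estimates from positions by central differences over ``window``.

    For frame spacing ``dt_f`` the half-window is ``k = max(1,
    round(window / 2 / dt_f))`` frames; interior estimates are
    ``(x[i+k] - x[i-k]) / (2 k dt_f)`` and endpoints use one-sided windows of
    the same total length.  Returns a new trajectory table with vx, vy filled.
    """
    df = traj.frame.sort_values(["agent_id", "t"], kind="mergesort").copy()
    vx = np.empty(len(df))
    vy = np.empty(len(df))
    row = 0
    for _, g in df.groupby("agent_id", sort=True):
        t = g["t"].to_numpy()
        steps = np.diff(t)
        if len(t) < 2:
            raise ValueError("track too short for velocity estimation")
        dt_f = float(np.median(steps))
        if not np.allclose(steps, dt_f, rtol=0, atol=1e-6):
            raise ValueError("non-uniform frame spacing; resample first")
        if dt_f > window / 2:
            raise ValueError(f"frame spacing {dt_f} exceeds half the window {window}")
        # half ties round up so a 0.76 s window at 25 fps spans 0.8 s, not 0.72
        k = max(1, int(np.floor(window / (2.0 * dt_f) + 0.5 + 1e-9)))
        m = len(t)
        if m < 2 * k + 1:
            raise ValueError(f"track of {m} frames shorter than the {2 * k + 1}-frame window")
        span = 2 * k * dt_f
        for col, out in (("x", vx), ("y", vy)):
            p = g[col].to_numpy()
            v = np.empty(m)
            v[k:m - k] = (p[2 * k:] - p[:m - 2 * k]) / span
            for i in range(k):  # one-sided windows of the same total length
                v[i] = (p[i + 2 * k] - p[i]) / span
                v[m - 1 - i] = (p[m - 1 - i] - p[m - 1 - i - 2 * k]) / span
            out[row:row + m] = v
        row += m
    df["vx"] = vx
    df["vy"] = vy
    from .simulator import TrajectoryTable
    meta = dict(traj.meta)
    meta["velocity_window"] = window
    return TrajectoryTable(frame=df, meta=meta)
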