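"""Rectangular arena geometry: wall identities, inward normals, tangent conventions.

The coordinate frame puts the origin at the arena centre, x along the long
(width) side and y along the short (height) side.  Each wall carries a unit
inward normal ``n_hat`` and a unit tangent ``t_plus`` obtained by rotating
``n_hat`` by -90 deg; following ``t_plus`` traverses the boundary
counterclockwise on every wall, so ``t_plus`` is the tangent of CCW
circulation and ``-t_plus`` that of CW circulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Arena",
    "WallFrame",
    "EscapedAgentError",
    "WALL_ORDER",
    "wall_frames",
    "mirror_state",
]

#: Fixed wall order used for tie-breaking in nearest-wall sorts.
WALL_ORDER = ("E", "N", "W", "S")


class EscapedAgentError(ValueError):
    """An agent position lies outside (or on) the arena boundary.

    During integration this signals a blow-up (time step too large); the
    offending agent id and time are attached when known.
    """

    def __init__(self, message: str, agent_id: int | None = None, time: float | None = None):
        super().__init__(message)
        self.agent_id = agent_id
        self.time = time


@dataclass(frozen=True)
class Arena:
    """Rectangular enclosure centred at the origin.

    Parameters
    ----------
    width : float
        Extent along x in metres (default 11.4).
    height : float
        Extent along y in metres (default 6.7).
    """

    width: float = 11.4
    height: float = 6.7
    walls: tuple[str, ...] = field(default=WALL_ORDER)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"arena sides must be positive, got {self.width} x {self.height}")

    @property
    def half_width(self) -> float:
        return self.width / 2.0

    @property
    def half_height(self) -> float:
        return self.height / 2.0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def corners(self) -> np.ndarray:
        """Corner coordinates in CCW order starting from (+x, +y), shape (4, 2)."""
        hw, hh = self.half_width, self.half_height
        return np.array([[hw, hh], [-hw, hh], [-hw, -hh], [hw, -hh]])

    def contains(self, positions: np.ndarray, strict: bool = True) -> np.ndarray:
        """Boolean mask of positions strictly inside (or inside-or-on) the arena."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        if strict:
            return (np.abs(p[:, 0]) < self.half_width) & (np.abs(p[:, 1]) < self.half_height)
        return (np.abs(p[:, 0]) <= self.half_width) & (np.abs(p[:, 1]) <= self.half_height)


def _rotate_minus_90(v: np.ndarray) -> np.ndarray:
    # (x, y) -> (y, -x)
    return np.array([v[1], -v[0]])


# Static wall data in the canonical frame: inward normal per wall id.
_WALL_NORMALS = {
    "E": np.array([-1.0, 0.0]),
    "N": np.array([0.0, -1.0]),
    "W": np.array([1.0, 0.0]),
    "S": np.array([0.0, 1.0]),
}


@dataclass(frozen=True)
class WallFrame:
    """Local frame of one wall as seen from an agent position.

    ``r_iw`` is the perpendicular distance from the agent centre to the wall,
    ``n_hat`` the unit inward normal, ``t_plus`` the CCW-circulation tangent
    (``n_hat`` rotated by -90 deg) and ``t_minus = -t_plus``.
    """

    wall_id: str
    r_iw: float
    n_hat: np.ndarray
    t_plus: np.ndarray

    @property
    def t_minus(self) -> np.ndarray:
        return -self.t_plus


def wall_distances(position: np.ndarray, arena: Arena) -> dict[str, float]:
    """Perpendicular distance from ``position`` to each wall, keyed by wall id."""
    x, y = float(position[0]), float(position[1])
    hw, hh = arena.half_width, arena.half_height
    return {"E": hw - x, "N": hh - y, "W": x + hw, "S": y + hh}


def wall_frames(position: np.ndarray, arena: Arena) -> list[WallFrame]:
    """All four wall frames at ``position``, sorted by distance ascending.

    Ties are broken by the fixed wall order E, N, W, S.  Raises
    :class:`EscapedAgentError` if the position is outside or on the boundary.
    """
    position = np.asarray(position, dtype=float)
    if not arena.contains(position[None, :], strict=True)[0]:
        raise EscapedAgentError(
            f"position {tuple(position)} is outside or on the boundary of the "
            f"{arena.width} x {arena.height} arena"
        )
    dists = wall_distances(position, arena)
    frames = [
        WallFrame(
            wall_id=w,
            r_iw=dists[w],
            n_hat=_WALL_NORMALS[w].copy(),
            t_plus=_rotate_minus_90(_WALL_NORMALS[w]),
        )
        for w in WALL_ORDER
    ]
    # stable sort keeps the E, N, W, S order among ties
    frames.sort(key=lambda f: f.r_iw)
    return frames


def mirror_state(
    positions: np.ndarray,
    velocities: np.ndarray | None = None,
    chiralities: np.ndarray | None = None,
):
    """Reflect a state about the x-axis (y -> -y) and flip chirality labels.

    An involution: applying it twice returns the original state.  A CCW
    rotating configuration maps to the CW one with the angular momentum
    negated exactly.
    """
    flip = np.array([1.0, -1.0])
    out_pos = np.asarray(positions, dtype=float) * flip
    out_vel = None if velocities is None else np.asarray(velocities, dtype=float) * flip
    out_chi = None if chiralities is None else -np.asarray(chiralities)
    return out_pos, out_vel, out_chi
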