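"""Plain-text trajectory round-tripping and field exports.

The canonical trajectory format is a comma-separated table with a mandatory
header ``t,agent_id,x,y,vx,vy,chirality`` (period decimal point).  A tolerant
reader accepts externally tracked exports via a column mapping and infers the
frame rate from the time stamps; files without velocity columns are flagged
as positions-only so that downstream code demands
:func:`~roamsim.observables.sliding_velocities` first.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import TRAJ_COLUMNS, TrajectoryTable

__all__ = ["write_trajectory", "read_trajectory", "write_field_grid"]

log = logging.getLogger("roamsim")


def write_trajectory(table: TrajectoryTable, path: str | Path,
                     sidecar: bool = True) -> None:
    """Write a trajectory as CSV; metadata goes to ``<path>.meta.json``.

    Coordinates are written with 17 significant digits so the round-trip is
    lossless.
    """
    path = Path(path)
    cols = [c for c in TRAJ_COLUMNS if c in table.frame.columns]
    table.frame[cols].to_csv(path, index=False, float_format="%.17g")
    if sidecar and table.meta:
        Path(str(path) + ".meta.json").write_text(
            json.dumps(table.meta, indent=2, default=str) + "\n")


def read_trajectory(path: str | Path, column_map: dict[str, str] | None = None,
                    resample: bool = False) -> TrajectoryTable:
    """Read a trajectory table, tolerating external export layouts.

    ``column_map`` maps file column names to canonical ones (e.g.
    ``{"frame_time": "t", "id": "agent_id"}``).  Non-uniform time steps raise
    a warning and, with ``resample=True``, the track is linearly resampled to
    the median spacing.  Malformed rows raise with the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("t", "agent_id", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: header-only file, no trajectory rows")
    for c in ("t", "x", "y"):
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {c!r} at line {line}")
        df[c] = pd.to_numeric(df[c])

    positions_only = not ("vx" in df.columns and "vy" in df.columns)
    if positions_only:
        df["vx"] = np.nan
        df["vy"] = np.nan
    if "chirality" not in df.columns:
        df["chirality"] = 0

    # frame-rate inference / uniformity check per agent
    frame_dt = None
    for aid, g in df.groupby("agent_id"):
        steps = np.diff(np.sort(g["t"].to_numpy()))
        if len(steps) == 0:
            continue
        med = float(np.median(steps))
        frame_dt = med if frame_dt is None else frame_dt
        if not np.allclose(steps, med, rtol=0, atol=1e-6):
            log.warning("%s: non-uniform time steps for agent %s", path, aid)
            if resample:
                df = _resample(df, med)
            else:
                break

    meta = {"source": str(path), "positions_only": positions_only,
            "frame_dt": frame_dt}
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return TrajectoryTable(frame=df[TRAJ_COLUMNS], meta=meta)


def _resample(df: pd.DataFrame, dt: float) -> pd.DataFrame:
    out = []
    for aid, g in df.groupby("agent_id"):
        g = g.sort_values("t")
        t = g["t"].to_numpy()
        grid = np.arange(t[0], t[-1] + dt / 2, dt)
        row = {"t": grid, "agent_id": aid,
               "chirality": g["chirality"].iloc[0]}
        for c in ("x", "y", "vx", "vy"):
            row[c] = np.interp(grid, t, g[c].to_numpy())
        out.append(pd.DataFrame(row))
    return pd.concat(out, ignore_index=True)


def write_field_grid(grid, prefix: str | Path) -> None:
    """Write field matrices as plain-text with a header line carrying the
    grid spacing and origin; one file per field."""
    prefix = Path(prefix)
    header = (f"spacing={grid.grid_spacing} omega={grid.omega} "
              f"x0={grid.x_centers[0]} y0={grid.y_centers[0]} "
              "rows=y-index cols=x-index")
    np.savetxt(str(prefix) + ".density.txt", grid.density, header=header)
    np.savetxt(str(prefix) + ".speed.txt", grid.speed, header=header)
    np.savetxt(str(prefix) + ".vx.txt", grid.velocity[:, :, 0], header=header)
    np.savetxt(str(prefix) + ".vy.txt", grid.velocity[:, :, 1], header=header)
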