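"""Phase-space exploration over (agent count x wall damping) cells.

Each cell ``(ped, gamma)`` is simulated ``reps`` times with seeds derived
deterministically from ``(seed_base, ped, gamma, rep)``; the per-run summary
is the burn-in-excluded time average of the angular momentum, and the cell
aggregate is the mean of its absolute value (the phase-diagram colour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .forces import ModelParams
from .geometry import Arena
from .observables import l_series, time_avg_L
from .simulator import SimConfig, run

__all__ = ["SweepSpec", "PhaseTable", "run_sweep", "cell_summary",
           "l_distributions", "sign_split_stats", "classify_distribution"]

log = logging.getLogger("roamsim")

PHASE_COLUMNS = ["ped", "gamma", "rep", "seed", "mean_L"]


def run_seed(seed_base: int, ped: int, gamma: float, rep: int) -> int:
    """Deterministic per-run seed; gamma keyed at millesimal resolution."""
    ss = np.random.SeedSequence((seed_base, ped, int(round(gamma * 1000)), rep))
    return int(ss.generate_state(1)[0])


@dataclass(frozen=True)
class SweepSpec:
    """Grid of (ped, gamma) cells plus the shared run protocol.

    The defaults are desk-scale (10 reps, 300 s runs with 100 s burn-in); the
    full protocol is 100 reps of 1000 s with 200 s burn-in over ped 8..34 and
    gamma 0..2 step 0.05.
    """

    ped_values: tuple[int, ...] = (12, 24)
    gamma_values: tuple[float, ...] = (0.0, 1.5)
    reps: int = 10
    tp_enabled: bool = False
    params: ModelParams = field(default_factory=ModelParams)
    config: SimConfig = field(default_factory=lambda: SimConfig(
        duration=300.0, burn_in=100.0))
    seed_base: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if len(self.ped_values) == 0 or len(self.gamma_values) == 0:
            raise ValueError("ped_values and gamma_values must be non-empty")

    @classmethod
    def paper_scale(cls, tp_enabled: bool = False, seed_base: int = 0) -> "SweepSpec":
        return cls(ped_values=tuple(range(8, 35)),
                   gamma_values=tuple(np.round(np.arange(0.0, 2.0001, 0.05), 3)),
                   reps=100, tp_enabled=tp_enabled,
                   config=SimConfig(duration=1000.0, burn_in=200.0),
                   seed_base=seed_base)


@dataclass
class PhaseTable:
    """Per-run sweep results (long format) with the spec that produced them."""

    frame: pd.DataFrame
    spec: SweepSpec | None = None
    series: dict = field(default_factory=dict)  # (ped, gamma, rep) -> LSeries


def cell_summary(table: PhaseTable) -> pd.DataFrame:
    """Aggregate per cell: mean |<L>| (phase-map colour), mean signed <L>,
    fraction of runs with <L> > 0, and rep count."""
    g = table.frame.groupby(["ped", "gamma"])
    out = g["mean_L"].agg(
        mean_abs_L=lambda s: s.abs().mean(),
        mean_L="mean",
        frac_positive=lambda s: (s > 0).mean(),
        n_reps="count",
    ).reset_index()
    return out


def run_sweep(spec: SweepSpec, arena: Arena | None = None,
              checkpoint: str | Path | None = None,
              keep_series: bool = False) -> PhaseTable:
    """Execute every (ped, gamma, rep) run and collect burn-in-excluded <L>.

    With ``checkpoint`` set, completed rows are appended to a CSV after every
    run and skipped on re-entry, so interrupted sweeps resume where they left
    off.  ``keep_series`` retains the full L(t) series per run (needed for
    pooled distributions).
    """
    arena = arena or Arena()
    params = spec.params.replace(tp_enabled=spec.tp_enabled)
    done: set[tuple[int, float, int]] = set()
    rows: list[dict] = []
    if checkpoint is not None:
        checkpoint = Path(checkpoint)
        if checkpoint.exists():
            prev = pd.read_csv(checkpoint)
            rows = prev.to_dict("records")
            done = {(int(r["ped"]), float(r["gamma"]), int(r["rep"])) for r in rows}
            log.info("sweep checkpoint: %d runs already done", len(done))
        else:
            checkpoint.parent.mkdir(parents=True, exist_ok=True)
            checkpoint.write_text(",".join(PHASE_COLUMNS) + "\n")

    series: dict = {}
    total = len(spec.ped_values) * len(spec.gamma_values) * spec.reps
    k = 0
    for ped in spec.ped_values:
        for gamma in spec.gamma_values:
            for rep in range(spec.reps):
                k += 1
                key = (int(ped), float(gamma), int(rep))
                if key in done:
                    continue
                seed = run_seed(spec.seed_base, ped, gamma, rep)
                cfg = spec.config.replace(n_agents=int(ped), seed=seed)
                prm = params.replace(gamma=float(gamma))
                traj = run(cfg, prm, arena)
                ls = l_series(traj)
                mean_l = time_avg_L(ls, cfg.burn_in)
                row = {"ped": int(ped), "gamma": float(gamma), "rep": int(rep),
                       "seed": seed, "mean_L": mean_l}
                rows.append(row)
                if keep_series:
                    series[key] = ls
                if checkpoint is not None:
                    with open(checkpoint, "a") as fh:
                        fh.write(f"{ped},{gamma},{rep},{seed},{mean_l!r}\n")
                log.info("sweep %d/%d ped=%d gamma=%.3g rep=%d <L>=%.4f",
                         k, total, ped, gamma, rep, mean_l)
    frame = pd.DataFrame(rows, columns=PHASE_COLUMNS).sort_values(
        ["ped", "gamma", "rep"], kind="mergesort").reset_index(drop=True)
    return PhaseTable(frame=frame, spec=spec, series=series)


def l_distributions(table: PhaseTable, cells, burn_in: float | None = None,
                    bins: int = 61, value_range: tuple[float, float] = (-1.5, 1.5)):
    """Pooled post-burn-in L(t) histograms for the requested cells.

    ``cells`` is an iterable of (ped, gamma); all reps of a cell are pooled.
    Returns ``{(ped, gamma): (counts, bin_edges, stats)}`` where ``stats`` is
    the sign-split summary of :func:`sign_split_stats`.
    """
    if not table.series:
        raise ValueError("PhaseTable has no retained L series; rerun with keep_series=True")
    if burn_in is None:
        burn_in = table.spec.config.burn_in if table.spec else 0.0
    out = {}
    for ped, gamma in cells:
        pooled = []
        for (p, g, _), ls in table.series.items():
            if p == int(ped) and np.isclose(g, gamma):
                pooled.append(ls.values[ls.times > burn_in])
        if not pooled:
            raise ValueError(f"no retained series for cell ({ped}, {gamma})")
        samples = np.concatenate(pooled)
        counts, edges = np.histogram(samples, bins=bins, range=value_range)
        out[(int(ped), float(gamma))] = (counts, edges, sign_split_stats(samples))
    return out


def sign_split_stats(samples: np.ndarray) -> dict:
    """Simple, explicit shape statistic for pooled L(t) samples.

    With ``s`` the pooled standard deviation, reports the fraction of frames
    below ``-s/2`` (``f_neg``), within ``[-s/2, s/2]`` (``f_center``) and
    above ``s/2`` (``f_pos``).  A distribution that is bimodal about 0 puts
    substantial weight on both outer bands and little in the centre; a single
    peak at 0 keeps the centre band heavy; a single positive peak empties the
    negative band.
    """
    samples = np.asarray(samples, dtype=float)
    s = float(samples.std())
    if s == 0.0:
        return {"std": 0.0, "f_neg": 0.0, "f_center": 1.0, "f_pos": 0.0,
                "mean": float(samples.mean())}
    half = s / 2.0
    return {
        "std": s,
        "f_neg": float((samples < -half).mean()),
        "f_center": float((np.abs(samples) <= half).mean()),
        "f_pos": float((samples > half).mean()),
        "mean": float(samples.mean()),
    }


def classify_distribution(stats: dict) -> str:
    """Classify pooled L(t) shape from :func:`sign_split_stats` output.

    * ``"bimodal"``: both outer bands >= 0.25 and centre band <= 0.25
      (mass piled symmetrically away from 0).
    * ``"single_positive"`` / ``"single_negative"``: one outer band >= 0.5
      with the opposite band <= 0.15 (a single peak displaced off 0).
    * ``"central"``: centre band >= 0.3 (single peak around 0; a zero-mean
      Gaussian gives ~0.38).
    * ``"indeterminate"`` otherwise.
    """
    f_neg, f_c, f_pos = stats["f_neg"], stats["f_center"], stats["f_pos"]
    if f_neg >= 0.25 and f_pos >= 0.25 and f_c <= 0.25:
        return "bimodal"
    if f_pos >= 0.5 and f_neg <= 0.15:
        return "single_positive"
    if f_neg >= 0.5 and f_pos <= 0.15:
        return "single_negative"
    if f_c >= 0.3:
        return "central"
    return "indeterminate"
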