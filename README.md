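# roamsim

Simulation and analysis of self-propelled agents roaming a rectangular
enclosure (11.4 m x 6.7 m by default). The model combines four force laws —
velocity relaxation toward a desired speed, long-range "social distancing"
repulsion with a Hertzian contact core, wall repulsion with an optional
dissipative (damping) term, and an agent-specific tangential
turning-preference force at walls — and the package provides the full
observable stack for studying the collective rotation that emerges:

* normalized angular momentum `L(t)` (the vortex order parameter) and its
  burn-in-excluded time average;
* disc-kernel coarse-grained density / velocity fields;
* Voronoi areas clipped exactly to the arena rectangle;
* wall-approach turn-event detection with CCW/CW labelling and handedness
  expectations;
* (agent count x damping) phase sweeps with deterministic per-run seeding,
  checkpointing and pooled `L(t)` distribution shape statistics.

The integration kernel is numba-compiled (forward Euler, `dt = 0.01 s`
default) and is tested for exact agreement with pure per-agent reference
force functions, bit-exact reproducibility, and bit-exact mirror
equivariance (a reflected initial state yields the reflected trajectory and
a negated `L(t)`, frame by frame).

## CLI

```sh
# one run: 24 agents, wall damping 1.5, no turning preference
roamsim simulate --ped 24 --gamma 1.5 --no-tp --duration 1000 \
    --burn-in 200 --seed 1 --out traj.csv

# L series, coarse-grained fields, Voronoi areas of a trajectory
roamsim analyze --traj traj.csv --burn-in 200 --out-prefix traj

# phase sweep over a (ped, gamma) grid, resumable via --checkpoint
roamsim sweep --ped 8:34:2 --gamma 0:2:0.5 --reps 10 --no-tp --out phase.csv

# turn-event detection and CCW/CW summary
roamsim turns --traj traj.csv --out events.csv

# synthetic trajectories with known ground truth
roamsim fixtures --kind rotating_ring --speed 1 --out ring.csv
```

Trajectories are plain CSV (`t,agent_id,x,y,vx,vy,chirality`) with a JSON
metadata sidecar; externally tracked tables (e.g. 25 fps exports with
positions only) are read via `--velocity-window`-based sliding-window
velocity estimation and a configurable column mapping
(`roamsim.io.read_trajectory`).

## Package layout

| module                | contents |
|-----------------------|----------|
| `roamsim.geometry`    | arena, wall frames (inward normals, CCW tangents), mirror reflection |
| `roamsim.forces`      | `ModelParams` and the four force laws as pure functions |
| `roamsim.engine`      | compiled forward-Euler kernel |
| `roamsim.simulator`   | run protocol, initialization, `TrajectoryTable` |
| `roamsim.observables` | `L(t)`, coarse-grained fields, Voronoi areas, sliding velocities |
| `roamsim.turning`     | turn-event eligibility, CCW/CW labelling, handedness arithmetic |
| `roamsim.sweep`       | phase-space sweeps, distribution shape statistics |
| `roamsim.fixtures`    | synthetic trajectories with analytic ground truth |
| `roamsim.io`          | CSV round-tripping, field exports |
| `roamsim.cli`         | `roamsim` command group |
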