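import numpy as np
import pandas as pd
import pytest

from roamsim.forces import ModelParams
from roamsim.geometry import Arena
from roamsim.simulator import SimConfig, run
from roamsim.sweep import SweepSpec, run_sweep

DESK_CONFIG = SimConfig(duration=300.0, burn_in=100.0)


@pytest.fixture(scope="session")
def ntp_table():
    """NTP cells of the scaled-down transition check (24 reps/cell).

    Returns ``(frame, series)`` covering cells (24, 0.0), (24, 1.5), (12, 1.5).
    """
    spec24 = SweepSpec(ped_values=(24,), gamma_values=(0.0, 1.5), reps=24,
                       config=DESK_CONFIG, seed_base=0)
    spec12 = SweepSpec(ped_values=(12,), gamma_values=(1.5,), reps=24,
                       config=DESK_CONFIG, seed_base=0)
    t24 = run_sweep(spec24, keep_series=True)
    t12 = run_sweep(spec12, keep_series=True)
    t24.series.update(t12.series)
    return pd.concat([t24.frame, t12.frame], ignore_index=True), t24.series


@pytest.fixture(scope="session")
def tp_table():
    """TP 60/40 cells, shared by symmetry-breaking and histogram tests."""
    spec = SweepSpec(ped_values=(24,), gamma_values=(0.0, 1.5), reps=10,
                     tp_enabled=True, config=DESK_CONFIG, seed_base=1)
    return run_sweep(spec, keep_series=True)


@pytest.fixture(scope="session")
def arena():
    return Arena()


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def short_run():
    """A short damped 24-agent trajectory shared by observable tests."""
    cfg = SimConfig(n_agents=24, duration=30.0, burn_in=5.0, seed=11)
    return run(cfg, ModelParams(gamma=1.5))
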