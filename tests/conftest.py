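import numpy as np
import pandas as pd
import pytest

from lcvar.data import EmaPanel, Schedule
from lcvar.synthetic import (
    SimulationSpec, flat_profiles, make_var_params, simulate_panel,
)


def make_panel(values_by_participant, schedule=None, variable_names=None):
    """Assemble an EmaPanel from {pid: (T, d) array-with-NaN} dicts."""
    first = next(iter(values_by_participant.values()))
    d = np.asarray(first).shape[1]
    variable_names = variable_names or [f"item_{j + 1}" for j in range(d)]
    frames = []
    for pid, vals in values_by_participant.items():
        vals = np.asarray(vals, dtype=float)
        T = len(vals)
        if schedule is None:
            beeps = 6
            days = int(np.ceil(T / beeps))
            sched = Schedule(days, beeps)
        else:
            sched = schedule
        B = sched.beeps_per_day
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "day": np.repeat(np.arange(1, sched.n_days + 1), B)[:T],
                    "beep": np.tile(np.arange(1, B + 1), sched.n_days)[:T],
                    "clock_time": np.tile(sched.beep_times, sched.n_days)[:T],
                    **{v: vals[:, j] for j, v in enumerate(variable_names)},
                }
            )
        )
        schedule = sched
    return EmaPanel(pd.concat(frames, ignore_index=True), schedule, variable_names)


@pytest.fixture(scope="session")
def two_cluster_panel():
    """Two groups of participants with opposite-sign cross-lagged dynamics."""
    m1 = make_var_params(2, 1, cross_effect=0.4, seed=1,
                         cross_pairs=[(0, 1, 1.0), (1, 0, 1.0)])
    m2 = make_var_params(2, 1, cross_effect=0.4, seed=2,
                         cross_pairs=[(0, 1, -1.0), (1, 0, -1.0)])
    spec = SimulationSpec(
        n_participants=16,
        cluster_models=[m1, m2],
        cluster_proportions=np.array([0.5, 0.5]),
        diurnal_profiles=flat_profiles(2, 6, 2),
        n_days=10,
        seed=42,
    )
    panel, truth = simulate_panel(spec)
    return panel, truth, (m1, m2)


@pytest.fixture(scope="session")
def complete_small_panel():
    """One fully observed participant, 2 days x 6 beeps, 3 variables."""
    rng = np.random.default_rng(0)
    vals = np.clip(50 + 10 * rng.standard_normal((12, 3)), 0, 100)
    return make_panel({"p1": vals})
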