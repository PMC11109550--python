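"""Shared fixtures: schedules and cached synthetic cohorts.

Heavier simulated objects are session-scoped so unit and acceptance
tests can share them without re-simulating.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import torquelearn as tl
from torquelearn.data_model import Domain, PeriodDef, PeriodKind, PeriodSchedule


@pytest.fixture(scope="session")
def tang_schedule():
    return tl.build_schedule("tang")


@pytest.fixture(scope="session")
def new_schedule():
    return tl.build_schedule("new")


@pytest.fixture(scope="session")
def learner_fly(new_schedule):
    """New-setup fly with a strong learned bias and optomotor coupling."""
    cfg = tl.FlyConfig(seed=42, learned_bias=0.5, om_coupling=0.6)
    return tl.simulate_fly(cfg, new_schedule, "left")


@pytest.fixture(scope="session")
def null_fly(tang_schedule):
    cfg = tl.FlyConfig(seed=7, learned_bias=0.0, heat_escape_factor=1.0)
    return tl.simulate_fly(cfg, tang_schedule, "left")


def make_torque_record(
    torque: np.ndarray,
    schedule: PeriodSchedule,
    punished: str = "left",
    rate_hz: float = 20.0,
    heat: np.ndarray | None = None,
    fly_id: str = "handmade",
) -> tl.ExperimentRecord:
    """Build a record directly from a torque array (for hand-built cases)."""
    n = len(torque)
    t = np.arange(n) / rate_hz
    trace = pd.DataFrame(
        {
            "t_s": t,
            "torque": np.asarray(torque, dtype=float),
            "heat": np.zeros(n, dtype=bool) if heat is None else heat,
            "stim": ["none"] * n,
        }
    )
    return tl.ExperimentRecord(
        fly_id=fly_id,
        punished_domain=Domain(punished),
        schedule=schedule,
        trace=trace,
    )


def two_period_schedule(kind2: PeriodKind = PeriodKind.TEST) -> PeriodSchedule:
    """Minimal training + second-period schedule for hand-built traces."""
    return PeriodSchedule(
        setup="tang",
        periods=(
            PeriodDef(index=1, kind=PeriodKind.TRAINING, duration_s=120.0, heat_on=True),
            PeriodDef(index=2, kind=kind2, duration_s=120.0),
        ),
    )
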