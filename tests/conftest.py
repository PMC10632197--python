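from datetime import datetime, timedelta

import pytest

from bdscreen.engine import run_screening, screen_positive_patients
from bdscreen.model import (
    ObsKind,
    ObservationEvent,
    PatientRecord,
    PLRState,
    ReferenceOutcome,
    Sex,
    sorted_events,
)
from bdscreen.simulate import SimulationConfig, simulate_cohort

T0 = datetime(2020, 3, 1, 10, 0)  # reference admission: 10:00


def ev(pid, hours, kind, value):
    """Event `hours` after T0."""
    return ObservationEvent(pid, T0 + timedelta(hours=hours), kind, value)


def mk_record(
    events,
    pid="p1",
    admission=T0,
    los_days=7.0,
    age=65.0,
    sex=Sex.MALE,
    outcome=None,
):
    outcome = outcome or ReferenceOutcome(brain_death_confirmed=False)
    return PatientRecord(
        patient_id=pid,
        age=age,
        sex=sex,
        admission_time=admission,
        discharge_time=admission + timedelta(days=los_days),
        events=sorted_events(events),
        outcome=outcome,
    )


def persistent_positive_events(pid, start_h, end_h, step_h=4):
    """Coma + bilaterally absent pupils charted every `step_h` hours."""
    events = []
    h = start_h
    while h <= end_h:
        events += [
            ev(pid, h, ObsKind.RASS, -5),
            ev(pid, h, ObsKind.GCS, 3),
            ev(pid, h, ObsKind.PLR_LEFT, PLRState.ABSENT),
            ev(pid, h, ObsKind.PLR_RIGHT, PLRState.ABSENT),
        ]
        h += step_h
    return events


@pytest.fixture(scope="session")
def sim_cohort_414():
    """Default-parameter cohort at the study's size, screened once."""
    config = SimulationConfig(n_patients=414, seed=20260928)
    records, outcomes, truth = simulate_cohort(config)
    log = run_screening(records)
    return config, records, outcomes, truth, log


@pytest.fixture(scope="session")
def sim_cohort_2000():
    """Large cohort for parameter-recovery checks."""
    config = SimulationConfig(n_patients=2000, seed=424242)
    records, outcomes, truth = simulate_cohort(config)
    log = run_screening(records)
    return config, records, outcomes, truth, log
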