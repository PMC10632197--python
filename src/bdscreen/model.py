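"""Domain types shared by the screening engine, statistics, simulator and I/O layers.

The vocabulary mirrors neurocritical-care flowsheet charting: Richmond
Agitation Sedation Scale (RASS, -5 unarousable to +4 combative), Glasgow Coma
Scale (GCS, 3 worst to 15), per-eye pupillary light reflex (PLR), ventilation
mode, intracranial pressure (ICP, mmHg), cerebral perfusion pressure (CPP,
mmHg), serum sodium (mmol/L) and cardiopulmonary-resuscitation (CPR) events.
Timestamps are timezone-naive at minute resolution, which is the granularity
of ICU flowsheets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from datetime import datetime, time, timedelta
from typing import Iterable, Optional, Sequence


class ObsKind(str, enum.Enum):
    """Kinds of timestamped clinical observations the screening rule reads."""

    RASS = "RASS"
    GCS = "GCS"
    PLR_LEFT = "PLR_LEFT"
    PLR_RIGHT = "PLR_RIGHT"
    VENT_CONTROLLED = "VENT_CONTROLLED"
    SPONT_BREATHING = "SPONT_BREATHING"
    ICP = "ICP"
    CPP = "CPP"
    SODIUM = "SODIUM"
    CPR = "CPR"


class PLRState(str, enum.Enum):
    """Charted state of one pupil's light reflex."""

    PRESENT = "present"
    ABSENT = "absent"
    NOT_ASSESSABLE = "not_assessable"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


def check_value(kind: ObsKind, value) -> Optional[str]:
    """Return a violation message if ``value`` is outside the domain of ``kind``.

    Booleans are not accepted where an integer scale is expected.
    """
    if kind is ObsKind.RASS:
        if not isinstance(value, int) or isinstance(value, bool) or not -5 <= value <= 4:
            return f"RASS value {value!r} outside integer range [-5, 4]"
    elif kind is ObsKind.GCS:
        if not isinstance(value, int) or isinstance(value, bool) or not 3 <= value <= 15:
            return f"GCS value {value!r} outside integer range [3, 15]"
    elif kind in (ObsKind.PLR_LEFT, ObsKind.PLR_RIGHT):
        try:
            PLRState(value)
        except ValueError:
            return f"{kind.value} value {value!r} not one of present/absent/not_assessable"
    elif kind in (ObsKind.VENT_CONTROLLED, ObsKind.SPONT_BREATHING, ObsKind.CPR):
        if not isinstance(value, bool):
            return f"{kind.value} value {value!r} is not boolean"
    elif kind in (ObsKind.ICP, ObsKind.CPP):
        if not isinstance(value, (int, float)) or isinstance(value, bool) or value < 0:
            return f"{kind.value} value {value!r} is not a non-negative pressure (mmHg)"
    elif kind is ObsKind.SODIUM:
        if not isinstance(value, (int, float)) or isinstance(value, bool) or value <= 0:
            return f"SODIUM value {value!r} is not a positive concentration (mmol/L)"
    else:  # pragma: no cover - exhaustive over the enum
        return f"unknown observation kind {kind!r}"
    return None


@dataclass(frozen=True, order=True)
class ObservationEvent:
    """One timestamped clinical measurement of one kind for one patient."""

    patient_id: str
    time: datetime
    kind: ObsKind = field(compare=True)
    value: object = field(compare=False)


@dataclass(frozen=True)
class ReferenceOutcome:
    """Reference-standard outcome from serial expert neurological assessment.

    ``brain_death_confirmed`` is the study's target condition; the formal
    guideline-based determination itself is represented only as this label
    plus its timestamp.
    """

    brain_death_confirmed: bool
    determination_time: Optional[datetime] = None
    died_in_icu: bool = False
    organ_donation: bool = False


@dataclass(frozen=True)
class PatientRecord:
    """A patient's admission window, ordered event stream and outcome."""

    patient_id: str
    age: float
    sex: Sex
    admission_time: datetime
    discharge_time: datetime
    events: tuple[ObservationEvent, ...]
    outcome: ReferenceOutcome


@dataclass(frozen=True)
class OptionalFlags:
    """Ancillary clinical/laboratory findings attached to a notification.

    Each flag is computable from events at or before the screening tick only
    (no lookahead): controlled mechanical ventilation without spontaneous
    breathing, ICP above 50 mmHg, CPP below 20 mmHg, serum sodium above
    160 mmol/L or a swing greater than 10 mmol/L within the trailing 24 h,
    and any CPR before or during the stay.
    """

    vent_no_spont_breathing: bool = False
    icp_above_50: bool = False
    cpp_below_20: bool = False
    sodium_above_160: bool = False
    sodium_delta_gt_10: bool = False
    cpr_any: bool = False


class ComaSource(str, enum.Enum):
    """Which scale(s) triggered the coma criterion at a tick."""

    RASS = "RASS"
    GCS = "GCS"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class TickResult:
    patient_id: str
    tick_time: datetime
    coma_met: bool
    coma_source: ComaSource
    plr_met: bool
    positive: bool
    flags: OptionalFlags

    def __post_init__(self):
        if self.positive != (self.coma_met and self.plr_met):
            raise ValueError("positive must equal (coma_met and plr_met)")


@dataclass(frozen=True)
class Notification:
    """One screening alert: demographic snapshot, tick time and flags."""

    patient_id: str
    tick_time: datetime
    is_repeat: bool
    age: float
    sex: Sex
    flags: OptionalFlags


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient-level 2x2 counts of screening result against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class IntervalEstimate:
    """A proportion with an optional two-sided confidence interval.

    ``method`` records how the bounds were obtained; ``none`` means the
    estimate (or its variance) was undefined and no bounds are reported.
    """

    point: Optional[float]
    lower: Optional[float] = None
    upper: Optional[float] = None
    method: str = "none"
    confidence: float = 0.95

    def __post_init__(self):
        if self.method == "none" and (self.lower is not None or self.upper is not None):
            raise ValueError("method 'none' carries no bounds")
        if self.lower is not None and self.upper is not None and self.point is not None:
            if not (self.lower - 1e-12 <= self.point <= self.upper + 1e-12):
                raise ValueError("interval does not contain the point estimate")


@dataclass(frozen=True)
class AccuracyReport:
    """The five diagnostic-accuracy metrics with their intervals and provenance."""

    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    ppv: IntervalEstimate
    npv: IntervalEstimate
    accuracy: IntervalEstimate
    matrix: ConfusionMatrix
    n1: int  # condition-positive patients
    n0: int  # condition-negative patients

    @property
    def prevalence(self) -> float:
        return self.n1 / (self.n1 + self.n0)


#: staleness defaults: bedside neuro checks are charted at least once per
#: 12-h screening cycle; labs and invasive pressures may be less frequent.
DEFAULT_STALENESS_HOURS = {
    ObsKind.RASS: 12.0,
    ObsKind.GCS: 12.0,
    ObsKind.PLR_LEFT: 12.0,
    ObsKind.PLR_RIGHT: 12.0,
    ObsKind.VENT_CONTROLLED: 24.0,
    ObsKind.SPONT_BREATHING: 24.0,
    ObsKind.ICP: 24.0,
    ObsKind.CPP: 24.0,
    ObsKind.SODIUM: 24.0,
}


@dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters of the cyclic screening rule.

    The rule fires when coma (RASS -4/-5 or GCS 3-6) coincides with
    bilaterally absent pupillary light reflexes. Ticks occur at fixed
    wall-clock anchor times every ``cadence_hours``.
    """

    cadence_hours: float = 12.0
    tick_anchors: tuple[time, ...] = (time(6, 0), time(18, 0))
    staleness_hours: dict = field(default_factory=lambda: dict(DEFAULT_STALENESS_HOURS))
    coma_rass: frozenset = frozenset({-4, -5})
    coma_gcs_max: int = 6
    icp_threshold: float = 50.0
    cpp_threshold: float = 20.0
    sodium_abs_threshold: float = 160.0
    sodium_delta_threshold: float = 10.0
    sodium_window_hours: float = 24.0

    def __post_init__(self):
        if self.cadence_hours <= 0:
            raise ValueError("cadence_hours must be positive")
        if not 3 <= self.coma_gcs_max <= 15:
            raise ValueError("coma_gcs_max must be within the GCS range [3, 15]")
        for name in ("icp_threshold", "cpp_threshold", "sodium_abs_threshold",
                     "sodium_delta_threshold", "sodium_window_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.tick_anchors:
            raise ValueError("at least one tick anchor is required")

    def staleness(self, kind: ObsKind) -> timedelta:
        return timedelta(hours=self.staleness_hours[kind])


def validate_record(record: PatientRecord) -> list[str]:
    """Check every type invariant of a :class:`PatientRecord`.

    Returns a list of human-readable violations (empty iff the record is
    valid). The validator reports; it never raises.
    """
    v: list[str] = []
    if record.age < 18:
        v.append(f"age {record.age} below the adult inclusion threshold of 18")
    if not isinstance(record.sex, Sex):
        v.append(f"sex {record.sex!r} is not a Sex value")
    if record.admission_time >= record.discharge_time:
        v.append("admission_time is not before discharge_time")
    for i, ev in enumerate(record.events):
        if ev.patient_id != record.patient_id:
            v.append(f"event {i}: patient_id {ev.patient_id!r} differs from record")
        if not (record.admission_time <= ev.time <= record.discharge_time):
            v.append(f"event {i} ({ev.kind.value}): time {ev.time} outside admission window")
        msg = check_value(ev.kind, ev.value)
        if msg is not None:
            v.append(f"event {i}: {msg}")
    for i in range(1, len(record.events)):
        if record.events[i].time < record.events[i - 1].time:
            v.append(f"event {i} out of chronological order")
            break
    out = record.outcome
    if out.brain_death_confirmed and out.determination_time is None:
        v.append("brain_death_confirmed without determination_time")
    if not out.brain_death_confirmed and out.determination_time is not None:
        v.append("determination_time present without brain_death_confirmed")
    if out.determination_time is not None and not (
        record.admission_time <= out.determination_time <= record.discharge_time
    ):
        v.append("determination_time outside admission window")
    return v


def sorted_events(events: Iterable[ObservationEvent]) -> tuple[ObservationEvent, ...]:
    """Canonical event ordering: (time, kind) within one patient."""
    return tuple(sorted(events, key=lambda e: (e.time, e.kind.value)))
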