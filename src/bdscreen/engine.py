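"""Cyclic screening of ICU event streams for clinical signs of impending brain death.

The rule fires at a tick when the patient is comatose (latest RASS of -4 or
-5, or latest GCS of 3-6) *and* the pupillary light reflex is charted absent
in both eyes. The screen runs at fixed wall-clock anchor times (06:00 and
18:00 by default, i.e. every 12 h) and dispatches one notification per
positive tick; all notifications after a patient's first are repeats.

Observed values count at a tick only if charted within a kind-specific
staleness window before the tick (12 h for bedside neuro checks, 24 h for
labs and pressures by default); missing or expired data never triggers the
rule, and an unassessable pupil on either side fails the pupil criterion.
"""

from __future__ import annotations

import statistics
from bisect import bisect_right
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    ComaSource,
    EngineConfig,
    Notification,
    ObsKind,
    ObservationEvent,
    OptionalFlags,
    PatientRecord,
    PLRState,
    TickResult,
)


class KindIndex:
    """Per-kind time index over one patient's sorted event stream."""

    def __init__(self, events: Sequence[ObservationEvent]):
        self._times: dict[ObsKind, list[datetime]] = {k: [] for k in ObsKind}
        self._values: dict[ObsKind, list] = {k: [] for k in ObsKind}
        last = None
        for ev in events:
            if last is not None and ev.time < last:
                raise ValueError("events must be sorted by time")
            last = ev.time
            self._times[ev.kind].append(ev.time)
            self._values[ev.kind].append(ev.value)

    def latest(self, kind: ObsKind, t: datetime, max_staleness: timedelta):
        """Most recent value of ``kind`` at or before ``t`` and no older than
        ``max_staleness``; ``None`` if absent or expired."""
        if kind not in self._times:
            raise KeyError(f"unknown observation kind: {kind!r}")
        times = self._times[kind]
        i = bisect_right(times, t)
        if i == 0:
            return None
        if t - times[i - 1] > max_staleness:
            return None
        return self._values[kind][i - 1]

    def values_in_window(self, kind: ObsKind, start: datetime, end: datetime) -> list:
        """Values of ``kind`` with time in the half-open window (start, end]."""
        times = self._times[kind]
        lo = bisect_right(times, start)
        hi = bisect_right(times, end)
        return self._values[kind][lo:hi]

    def any_true_before(self, kind: ObsKind, t: datetime) -> bool:
        times = self._times[kind]
        hi = bisect_right(times, t)
        return any(self._values[kind][i] for i in range(hi))


def latest_value(
    events: Sequence[ObservationEvent],
    kind: ObsKind,
    t: datetime,
    max_staleness: timedelta,
):
    """Most recent value of ``kind`` at or before ``t`` within ``max_staleness``.

    ``events`` must be sorted by time. Returns ``None`` when no sufficiently
    recent observation exists. Raises ``KeyError`` for an unknown kind.
    """
    if not isinstance(kind, ObsKind):
        raise KeyError(f"unknown observation kind: {kind!r}")
    return KindIndex(events).latest(kind, t, max_staleness)


def evaluate_coma_criterion(
    index: KindIndex | Sequence[ObservationEvent],
    t: datetime,
    config: EngineConfig,
) -> tuple[bool, ComaSource]:
    """Coma per the screening rule: latest RASS in {-4, -5} or latest GCS in [3, 6].

    Absent or stale values never trigger. Returns the criterion together with
    which scale(s) fired.
    """
    idx = index if isinstance(index, KindIndex) else KindIndex(index)
    rass = idx.latest(ObsKind.RASS, t, config.staleness(ObsKind.RASS))
    gcs = idx.latest(ObsKind.GCS, t, config.staleness(ObsKind.GCS))
    by_rass = rass is not None and rass in config.coma_rass
    by_gcs = gcs is not None and 3 <= gcs <= config.coma_gcs_max
    if by_rass and by_gcs:
        return True, ComaSource.BOTH
    if by_rass:
        return True, ComaSource.RASS
    if by_gcs:
        return True, ComaSource.GCS
    return False, ComaSource.NONE


def evaluate_pupil_criterion(
    index: KindIndex | Sequence[ObservationEvent],
    t: datetime,
    config: EngineConfig,
) -> bool:
    """Bilaterally absent pupillary light reflexes, both charted within staleness.

    An undocumented or not-assessable pupil on either side fails the criterion:
    the screen must not fire on missing data.
    """
    idx = index if isinstance(index, KindIndex) else KindIndex(index)
    left = idx.latest(ObsKind.PLR_LEFT, t, config.staleness(ObsKind.PLR_LEFT))
    right = idx.latest(ObsKind.PLR_RIGHT, t, config.staleness(ObsKind.PLR_RIGHT))
    return left == PLRState.ABSENT and right == PLRState.ABSENT


def compute_optional_flags(
    index: KindIndex | Sequence[ObservationEvent],
    t: datetime,
    config: EngineConfig,
) -> OptionalFlags:
    """Ancillary findings reported alongside a notification.

    Thresholds are strict: ICP above 50 mmHg, CPP below 20 mmHg, sodium above
    160 mmol/L. The sodium swing flag needs at least two values inside the
    trailing 24-h window and compares their max - min against 10 mmol/L.
    """
    idx = index if isinstance(index, KindIndex) else KindIndex(index)
    vent = idx.latest(ObsKind.VENT_CONTROLLED, t, config.staleness(ObsKind.VENT_CONTROLLED))
    spont = idx.latest(ObsKind.SPONT_BREATHING, t, config.staleness(ObsKind.SPONT_BREATHING))
    icp = idx.latest(ObsKind.ICP, t, config.staleness(ObsKind.ICP))
    cpp = idx.latest(ObsKind.CPP, t, config.staleness(ObsKind.CPP))
    sodium = idx.latest(ObsKind.SODIUM, t, config.staleness(ObsKind.SODIUM))
    window = idx.values_in_window(
        ObsKind.SODIUM, t - timedelta(hours=config.sodium_window_hours), t
    )
    return OptionalFlags(
        vent_no_spont_breathing=bool(vent) and spont is False,
        icp_above_50=icp is not None and icp > config.icp_threshold,
        cpp_below_20=cpp is not None and cpp < config.cpp_threshold,
        sodium_above_160=sodium is not None and sodium > config.sodium_abs_threshold,
        sodium_delta_gt_10=len(window) >= 2
        and (max(window) - min(window)) > config.sodium_delta_threshold,
        cpr_any=idx.any_true_before(ObsKind.CPR, t),
    )


def evaluate_tick(index: KindIndex, record: PatientRecord, t: datetime,
                  config: EngineConfig) -> TickResult:
    coma_met, source = evaluate_coma_criterion(index, t, config)
    plr_met = evaluate_pupil_criterion(index, t, config)
    return TickResult(
        patient_id=record.patient_id,
        tick_time=t,
        coma_met=coma_met,
        coma_source=source,
        plr_met=plr_met,
        positive=coma_met and plr_met,
        flags=compute_optional_flags(index, t, config),
    )


def tick_times(record: PatientRecord, config: EngineConfig) -> list[datetime]:
    """Screening ticks for one admission.

    Ticks fall on the configured wall-clock anchors, strictly after admission
    and at or before discharge; when brain death was formally determined,
    screening stops at the determination time so post-mortem charting cannot
    generate alerts.
    """
    end = record.discharge_time
    det = record.outcome.determination_time
    if record.outcome.brain_death_confirmed and det is not None:
        end = min(end, det)
    anchors = sorted(set(config.tick_anchors))
    ticks: list[datetime] = []
    day = record.admission_time.date()
    while True:
        made_progress = False
        for anchor in anchors:
            t = datetime.combine(day, anchor)
            if t > end:
                return ticks
            if t > record.admission_time:
                ticks.append(t)
            made_progress = True
        if not made_progress:  # pragma: no cover - anchors is non-empty
            return ticks
        day = day + timedelta(days=1)


def run_screening(
    records: Iterable[PatientRecord],
    config: EngineConfig | None = None,
) -> list[Notification]:
    """Run the cyclic screen over a cohort and return the notification log.

    One notification per positive tick; ``is_repeat`` is False only for a
    patient's first. The log is sorted by (tick_time, patient_id) and is a
    deterministic function of the inputs. Raises ``ValueError`` if one
    patient_id appears on more than one record.
    """
    config = config or EngineConfig()
    seen: set[str] = set()
    notifications: list[Notification] = []
    for record in records:
        if record.patient_id in seen:
            raise ValueError(
                f"patient_id {record.patient_id!r} has more than one admission record"
            )
        seen.add(record.patient_id)
        index = KindIndex(record.events)
        first = True
        for t in tick_times(record, config):
            result = evaluate_tick(index, record, t, config)
            if result.positive:
                notifications.append(
                    Notification(
                        patient_id=record.patient_id,
                        tick_time=t,
                        is_repeat=not first,
                        age=record.age,
                        sex=record.sex,
                        flags=result.flags,
                    )
                )
                first = False
    notifications.sort(key=lambda n: (n.tick_time, n.patient_id))
    return notifications


@dataclass(frozen=True)
class PatientNotificationSummary:
    patient_id: str
    first_time: datetime
    total: int
    repeats: int
    gaps_hours: tuple[float, ...]


@dataclass(frozen=True)
class CohortNotificationSummary:
    n_screen_positive: int
    total_notifications: int
    total_repeats: int
    counts_median: Optional[float]
    counts_iqr: tuple[Optional[float], Optional[float]]
    counts_mean: Optional[float]
    counts_sd: Optional[float]
    gaps_median_hours: Optional[float]
    gaps_iqr_hours: tuple[Optional[float], Optional[float]]
    gaps_mean_hours: Optional[float]
    gaps_sd_hours: Optional[float]


def summarize_notifications(
    log: Sequence[Notification],
) -> tuple[dict[str, PatientNotificationSummary], CohortNotificationSummary]:
    """Per-patient and cohort-level notification bookkeeping.

    Gaps are consecutive inter-notification intervals within a patient, in
    hours. Spread statistics use the sample standard deviation and
    quartile-interpolated IQR.
    """
    per: dict[str, list[Notification]] = {}
    for n in log:
        per.setdefault(n.patient_id, []).append(n)
    summaries: dict[str, PatientNotificationSummary] = {}
    all_gaps: list[float] = []
    for pid, ns in per.items():
        ns.sort(key=lambda n: n.tick_time)
        gaps = tuple(
            (b.tick_time - a.tick_time).total_seconds() / 3600.0
            for a, b in zip(ns, ns[1:])
        )
        all_gaps.extend(gaps)
        summaries[pid] = PatientNotificationSummary(
            patient_id=pid,
            first_time=ns[0].tick_time,
            total=len(ns),
            repeats=len(ns) - 1,
            gaps_hours=gaps,
        )
    counts = [s.total for s in summaries.values()]

    def _stats(xs: list[float]):
        if not xs:
            return None, (None, None), None, None
        arr = np.asarray(xs, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        sd = float(statistics.stdev(arr)) if len(arr) > 1 else 0.0
        return float(med), (float(q1), float(q3)), float(arr.mean()), sd

    c_med, c_iqr, c_mean, c_sd = _stats([float(c) for c in counts])
    g_med, g_iqr, g_mean, g_sd = _stats(all_gaps)
    cohort = CohortNotificationSummary(
        n_screen_positive=len(summaries),
        total_notifications=len(log),
        total_repeats=sum(s.repeats for s in summaries.values()),
        counts_median=c_med,
        counts_iqr=c_iqr,
        counts_mean=c_mean,
        counts_sd=c_sd,
        gaps_median_hours=g_med,
        gaps_iqr_hours=g_iqr,
        gaps_mean_hours=g_mean,
        gaps_sd_hours=g_sd,
    )
    return summaries, cohort


def screen_positive_patients(log: Sequence[Notification]) -> set[str]:
    """Patients with at least one notification during the admission."""
    return {n.patient_id for n in log}


def repeat_detected_patients(log: Sequence[Notification]) -> set[str]:
    """Patients with more than one notification (at least one repeat)."""
    counts: dict[str, int] = {}
    for n in log:
        counts[n.patient_id] = counts.get(n.patient_id, 0) + 1
    return {pid for pid, c in counts.items() if c >= 2}
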