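"""Synthetic neurocritical-care cohorts for end-to-end testing of the screen.

The generator emulates the statistical structure of a 12-bed neurocritical
care unit observed over a year: ~1.9% of admissions progress to confirmed
brain death, while roughly one in nine of the remaining patients exhibits a
transient screening-positive pattern — typically deep analgosedation with
transiently unassessable or absent pupillary reflexes — that produces a
false-positive alert. Charting follows ICU flowsheet practice: bedside neuro
checks (RASS, GCS, per-eye pupillary reflex) every few hours with jitter,
ventilation status and serum sodium at lower cadence.

Patients are generated by designed class so that engine output can be scored
against ground truth:

* ``brain_death`` — persistent coma with bilaterally absent pupillary
  reflexes from a random onset until the formal determination time, which is
  drawn as first-alert time plus a truncated-normal delay. Persistence
  guarantees at least one screening tick inside the episode.
* ``false_positive`` — one or more transient episodes aligned to screening
  ticks, each long enough to be charted before the tick and reverting
  afterwards, so the designed number of alerts is exact.
* ``true_negative`` — never satisfies coma and bilateral pupil absence
  within the same staleness window; sedated true negatives do reach
  coma-level RASS/GCS but keep at least one reactive pupil.
* ``fn_pattern`` (optional stress mode, off by default) — a condition-
  positive patient whose positive findings flicker between ticks and are
  re-charted as recovered before the next tick, so the screen never fires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ObsKind,
    ObservationEvent,
    PatientRecord,
    PLRState,
    ReferenceOutcome,
    Sex,
    sorted_events,
)

_EPOCH = datetime(2020, 2, 1)
_ANCHORS = (time(6, 0), time(18, 0))  # must match the engine's default ticks


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Defaults reproduce the cohort composition of a year of neurocritical-care
    admissions: prevalence of confirmed brain death 1.9%, false-positive
    pattern rate 46/406 among non-brain-death patients, 34/54 of screen
    positives detected repeatedly, age 70.8 +/- 14.8 years (adults only),
    45.9% female, length of stay 9.1 +/- 8.6 days, and an alert-to-
    determination delay of 3.6 +/- 3.2 days (left-truncated at half a day).
    Sedation and ventilation probabilities are class-conditional so the
    sedation-screening association (odds ratio ~6) is built in.
    """

    n_patients: int = 414
    prevalence_bd: float = 0.019
    p_false_positive_pattern: float = 46 / 406
    p_repeat_given_positive: float = 34 / 54
    mean_days_notification_to_bd: float = 3.6
    sd_days_notification_to_bd: float = 3.2
    min_days_notification_to_bd: float = 0.5
    los_mean_days: float = 9.1
    los_sd_days: float = 8.6
    los_min_days: float = 1.0
    age_mean: float = 70.8
    age_sd: float = 14.8
    age_min: float = 18.0
    p_female: float = 0.459
    charting_interval_hours: float = 4.0
    diagnosis_mix: dict = field(
        default_factory=lambda: {
            "ischemic_stroke": 0.701,
            "intracerebral_hemorrhage": 0.128,
            "seizure": 0.082,
            "meningoencephalitis": 0.031,
            "other": 0.058,
        }
    )
    p_sedation_given_fp: float = 0.891
    p_sedation_given_tn: float = 0.567
    p_sedation_given_bd: float = 7 / 8
    p_vent_given_fp: float = 0.87
    p_vent_given_tn: float = 0.35
    p_vent_given_bd: float = 1.0
    # flag frequencies among screen positives
    p_icp_flag: float = 6 / 54
    p_cpp_flag: float = 4 / 54
    p_sodium_abs_flag: float = 7 / 54
    p_sodium_delta_flag: float = 25 / 54
    p_cpr_flag: float = 6 / 54
    p_death_given_fp: float = 0.5
    p_death_given_tn: float = 0.15
    p_donation_given_bd: float = 7 / 8
    enable_fn_pattern: bool = False
    p_fn_pattern: float = 0.0
    seed: int = 0

    def __post_init__(self):
        probs = [
            self.prevalence_bd, self.p_false_positive_pattern,
            self.p_repeat_given_positive, self.p_female,
            self.p_sedation_given_fp, self.p_sedation_given_tn,
            self.p_sedation_given_bd, self.p_vent_given_fp,
            self.p_vent_given_tn, self.p_vent_given_bd, self.p_fn_pattern,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


def _minute(dt: datetime) -> datetime:
    return dt.replace(second=0, microsecond=0)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return x
    return lower


def _next_anchor(t: datetime) -> datetime:
    """Earliest screening tick strictly after ``t`` on the default grid."""
    day = t.date()
    while True:
        for anchor in _ANCHORS:
            cand = datetime.combine(day, anchor)
            if cand > t:
                return cand
        day = day + timedelta(days=1)


def _anchors_between(start: datetime, end: datetime) -> list[datetime]:
    out = []
    t = _next_anchor(start)
    while t <= end:
        out.append(t)
        t = t + timedelta(hours=12)
    return out


@dataclass
class _Profile:
    """Per-patient static covariates and designed trajectory."""

    designed_class: str
    sedation: bool
    ventilated: bool
    cpr: bool
    icp_flag: bool
    cpp_flag: bool
    sodium_abs_flag: bool
    sodium_delta_flag: bool
    episodes: list[tuple[datetime, datetime]]
    designed_ticks: int


def _in_episode(t: datetime, episodes: list[tuple[datetime, datetime]]) -> bool:
    return any(a <= t <= b for a, b in episodes)


def _chart_times(rng, start: datetime, end: datetime, interval_h: float) -> list[datetime]:
    """Charting grid with +/- 1 h jitter, clipped to the stay; includes start."""
    times = [start]
    t = start
    while True:
        t = t + timedelta(hours=interval_h)
        if t >= end:
            break
        jitter = timedelta(hours=float(rng.uniform(-1.0, 1.0)))
        tt = min(max(t + jitter, start), end)
        times.append(tt)
    return sorted(_minute(x) for x in times)


def simulate_patient(
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str,
    force_outcome: Optional[str] = None,
) -> tuple[PatientRecord, dict]:
    """One synthetic admission. Returns the record and its truth-log row.

    ``force_outcome`` pins the designed class (``brain_death``,
    ``false_positive``, ``true_negative`` or ``fn_pattern``) instead of
    drawing it from the configured mixture.
    """
    if force_outcome is None:
        u = rng.random()
        if u < config.prevalence_bd:
            cls = "brain_death"
        else:
            v = rng.random()
            if config.enable_fn_pattern and v < config.p_fn_pattern:
                cls = "fn_pattern"
            elif v < config.p_fn_pattern + config.p_false_positive_pattern:
                cls = "false_positive"
            else:
                cls = "true_negative"
    else:
        cls = force_outcome
        if cls not in ("brain_death", "false_positive", "true_negative", "fn_pattern"):
            raise ValueError(f"unknown force_outcome {cls!r}")

    age = _truncnorm(rng, config.age_mean, config.age_sd, config.age_min)
    sex = Sex.FEMALE if rng.random() < config.p_female else Sex.MALE
    diagnoses = list(config.diagnosis_mix)
    weights = np.array([config.diagnosis_mix[d] for d in diagnoses], dtype=float)
    diagnosis = diagnoses[int(rng.choice(len(diagnoses), p=weights / weights.sum()))]
    admission = _minute(
        _EPOCH
        + timedelta(days=float(rng.uniform(0, 365)), minutes=float(rng.uniform(0, 24 * 60)))
    )

    if cls == "brain_death":
        sedation = rng.random() < config.p_sedation_given_bd
        ventilated = rng.random() < config.p_vent_given_bd
    elif cls == "false_positive":
        sedation = rng.random() < config.p_sedation_given_fp
        ventilated = rng.random() < config.p_vent_given_fp
    else:
        sedation = rng.random() < config.p_sedation_given_tn
        ventilated = rng.random() < config.p_vent_given_tn

    is_designed_positive = cls in ("brain_death", "false_positive")
    icp_flag = is_designed_positive and rng.random() < config.p_icp_flag
    cpp_flag = is_designed_positive and rng.random() < config.p_cpp_flag
    na_abs_flag = is_designed_positive and rng.random() < config.p_sodium_abs_flag
    na_delta_flag = is_designed_positive and rng.random() < config.p_sodium_delta_flag
    cpr_flag = is_designed_positive and rng.random() < config.p_cpr_flag

    episodes: list[tuple[datetime, datetime]] = []
    designed_ticks = 0
    determination: Optional[datetime] = None

    if cls == "brain_death":
        onset = _minute(admission + timedelta(hours=float(rng.uniform(6, 48))))
        first_tick = _next_anchor(onset)
        delay_days = _truncnorm(
            rng,
            config.mean_days_notification_to_bd,
            config.sd_days_notification_to_bd,
            config.min_days_notification_to_bd,
        )
        determination = _minute(first_tick + timedelta(days=delay_days))
        episodes = [(onset, determination)]
        designed_ticks = len(
            [t for t in _anchors_between(admission, determination) if t > onset]
        )
        discharge = determination
        outcome = ReferenceOutcome(
            brain_death_confirmed=True,
            determination_time=determination,
            died_in_icu=True,
            organ_donation=rng.random() < config.p_donation_given_bd,
        )
    else:
        if cls == "false_positive":
            repeat = rng.random() < config.p_repeat_given_positive
            want = 1 if not repeat else 2 + int(rng.poisson(2.5))
            for _ in range(200):
                los = _truncnorm(rng, config.los_mean_days, config.los_sd_days,
                                 max(config.los_min_days, 2.0))
                discharge = _minute(admission + timedelta(days=los))
                usable = [
                    t
                    for t in _anchors_between(admission, discharge)
                    if t - timedelta(hours=4) > admission
                    and t + timedelta(hours=8) < discharge
                ]
                need = 2 if repeat else 1
                if len(usable) >= need:
                    break
            else:
                raise RuntimeError("could not place a screening episode within the stay")
            k = min(want, len(usable)) if repeat else 1
            start_i = int(rng.integers(0, len(usable) - k + 1))
            run = usable[start_i : start_i + k]
            # cover ticks run[0]..run[-1] contiguously; chart reverts after
            episodes = [(run[0] - timedelta(hours=3), run[-1])]
            designed_ticks = k
        elif cls == "fn_pattern":
            los = _truncnorm(rng, config.los_mean_days, config.los_sd_days,
                             max(config.los_min_days, 3.0))
            discharge = _minute(admission + timedelta(days=los))
            ticks = _anchors_between(admission, discharge - timedelta(hours=12))
            if ticks:
                base = ticks[int(rng.integers(0, len(ticks)))]
                # flicker strictly between ticks, recovered well before the next
                episodes = [(base + timedelta(hours=1), base + timedelta(hours=3))]
            determination = discharge
        else:
            los = _truncnorm(rng, config.los_mean_days, config.los_sd_days,
                             config.los_min_days)
            discharge = _minute(admission + timedelta(days=los))
        if cls == "fn_pattern":
            outcome = ReferenceOutcome(
                brain_death_confirmed=True,
                determination_time=determination,
                died_in_icu=True,
                organ_donation=False,
            )
        else:
            p_death = (
                config.p_death_given_fp if cls == "false_positive" else config.p_death_given_tn
            )
            outcome = ReferenceOutcome(
                brain_death_confirmed=False,
                determination_time=None,
                died_in_icu=rng.random() < p_death,
                organ_donation=False,
            )

    events = _chart_events(
        config, rng, patient_id, admission, discharge, episodes,
        sedation=sedation, ventilated=ventilated, cpr=cpr_flag,
        icp_flag=icp_flag, cpp_flag=cpp_flag,
        na_abs_flag=na_abs_flag, na_delta_flag=na_delta_flag,
        guard_bilateral=(cls == "true_negative"),
    )
    record = PatientRecord(
        patient_id=patient_id,
        age=round(age, 1),
        sex=sex,
        admission_time=admission,
        discharge_time=discharge,
        events=sorted_events(events),
        outcome=outcome,
    )
    truth = {
        "patient_id": patient_id,
        "designed_class": cls,
        "designed_ticks": designed_ticks,
        "analgosedation": sedation,
        "ventilated": ventilated,
        "diagnosis": diagnosis,
        "brain_death": outcome.brain_death_confirmed,
    }
    return record, truth


def _chart_events(
    config: SimulationConfig,
    rng: np.random.Generator,
    pid: str,
    admission: datetime,
    discharge: datetime,
    episodes: list[tuple[datetime, datetime]],
    *,
    sedation: bool,
    ventilated: bool,
    cpr: bool,
    icp_flag: bool,
    cpp_flag: bool,
    na_abs_flag: bool,
    na_delta_flag: bool,
    guard_bilateral: bool,
) -> list[ObservationEvent]:
    """Flowsheet charting consistent with the designed trajectory.

    Neuro checks run on the jittered charting grid plus a forced chart at
    each episode start (so an episode is documented before its tick) and one
    right after each episode end (so recovery overrides stale positive
    findings before the next tick).
    """
    ev: list[ObservationEvent] = []

    def add(t: datetime, kind: ObsKind, value) -> None:
        if admission <= t <= discharge:
            ev.append(ObservationEvent(pid, _minute(t), kind, value))

    neuro_times = set(_chart_times(rng, admission, discharge, config.charting_interval_hours))
    for a, b in episodes:
        neuro_times.add(_minute(a))
        neuro_times.add(_minute(min(b + timedelta(minutes=30), discharge)))

    for t in sorted(neuro_times):
        positive = _in_episode(t, episodes)
        if positive:
            rass = -5
            gcs = 3
            plr_l = plr_r = PLRState.ABSENT
        elif sedation:
            rass = int(rng.integers(-5, -2))  # deep sedation: RASS -5..-3
            gcs = int(rng.integers(3, 9))
            # sedation can blunt a single pupil, never both
            one_sided = rng.random() < 0.15
            blunt = PLRState.NOT_ASSESSABLE if rng.random() < 0.5 else PLRState.ABSENT
            if one_sided:
                if rng.random() < 0.5:
                    plr_l, plr_r = blunt, PLRState.PRESENT
                else:
                    plr_l, plr_r = PLRState.PRESENT, blunt
            else:
                plr_l = plr_r = PLRState.PRESENT
        else:
            rass = int(rng.integers(-2, 2))
            gcs = int(rng.integers(9, 16))
            plr_l = plr_r = PLRState.PRESENT
        if guard_bilateral and plr_l == PLRState.ABSENT and plr_r == PLRState.ABSENT:
            plr_r = PLRState.PRESENT  # pragma: no cover - unreachable by construction
        add(t, ObsKind.RASS, rass)
        add(t, ObsKind.GCS, gcs)
        add(t, ObsKind.PLR_LEFT, plr_l)
        add(t, ObsKind.PLR_RIGHT, plr_r)

    if ventilated:
        for t in _chart_times(rng, admission, discharge, 12.0):
            add(t, ObsKind.VENT_CONTROLLED, True)
            add(t, ObsKind.SPONT_BREATHING, bool(rng.random() < 0.1))

    if cpr:
        add(admission, ObsKind.CPR, True)

    # serum sodium: mild random walk around 140 mmol/L every ~12 h
    sodium_times = _chart_times(rng, admission, discharge, 12.0)
    na = float(rng.normal(140.0, 3.0))
    for t in sodium_times:
        na += float(rng.normal(0.0, 1.5))
        add(t, ObsKind.SODIUM, round(na, 1))
    if episodes and (na_abs_flag or na_delta_flag):
        a = episodes[0][0]
        if na_delta_flag:
            add(a - timedelta(hours=10), ObsKind.SODIUM, 146.0)
        if na_abs_flag:
            add(a, ObsKind.SODIUM, round(float(rng.uniform(161.0, 168.0)), 1))
        else:
            add(a, ObsKind.SODIUM, 158.0)

    if icp_flag and episodes:
        add(episodes[0][0], ObsKind.ICP, round(float(rng.uniform(52.0, 75.0)), 1))
    if cpp_flag and episodes:
        add(episodes[0][0], ObsKind.CPP, round(float(rng.uniform(5.0, 18.0)), 1))
    return ev


def simulate_cohort(
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> tuple[list[PatientRecord], dict[str, ReferenceOutcome], pd.DataFrame]:
    """Generate ``config.n_patients`` independent admissions.

    Returns the records, the per-patient reference outcomes, and a truth log
    recording each patient's designed class and covariates so engine output
    can be scored against design. Reproducible under the seed (``config.seed``
    unless overridden).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    width = max(4, len(str(max(config.n_patients, 1))))
    records: list[PatientRecord] = []
    truth_rows: list[dict] = []
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        rec, truth = simulate_patient(config, rng, pid)
        records.append(rec)
        truth_rows.append(truth)
    outcomes = {r.patient_id: r.outcome for r in records}
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "designed_class", "designed_ticks",
            "analgosedation", "ventilated", "diagnosis", "brain_death",
        ],
    )
    return records, outcomes, truth


@dataclass(frozen=True)
class CalibrationCheck:
    name: str
    observed: float
    expected: float
    tolerance: float
    ok: bool


@dataclass(frozen=True)
class CalibrationReport:
    checks: tuple[CalibrationCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.ok for c in self.checks)


def _binom_check(name: str, count: int, n: int, p: float) -> CalibrationCheck:
    obs = count / n if n else float("nan")
    tol = 3.0 * math.sqrt(p * (1.0 - p) / n) if n else float("inf")
    return CalibrationCheck(name, obs, p, tol, ok=bool(n) and abs(obs - p) <= tol)


def calibration_check(
    screen_positive: set[str],
    repeat_detected: set[str],
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> CalibrationReport:
    """Score engine output against the generative design.

    Designed persistent positives (brain-death and false-positive patterns)
    must all be detected — engine sensitivity 1.0 on design. Empirical
    prevalence, false-positive rate among non-brain-death patients, and the
    repeat fraction among designed false positives are compared to their
    configured values with a 3-sigma binomial tolerance.
    """
    bd = truth[truth.designed_class == "brain_death"]
    fp = truth[truth.designed_class == "false_positive"]
    non_bd = truth[~truth.designed_class.isin(["brain_death", "fn_pattern"])]
    checks = []
    n_bd_detected = int(bd.patient_id.isin(screen_positive).sum())
    checks.append(
        CalibrationCheck(
            "designed_brain_death_detected",
            observed=n_bd_detected / len(bd) if len(bd) else 1.0,
            expected=1.0,
            tolerance=0.0,
            ok=n_bd_detected == len(bd),
        )
    )
    n_fp_detected = int(fp.patient_id.isin(screen_positive).sum())
    checks.append(
        CalibrationCheck(
            "designed_false_positive_detected",
            observed=n_fp_detected / len(fp) if len(fp) else 1.0,
            expected=1.0,
            tolerance=0.0,
            ok=n_fp_detected == len(fp),
        )
    )
    checks.append(
        _binom_check("prevalence", int(truth.brain_death.sum()), len(truth),
                     config.prevalence_bd)
    )
    fp_count = int(non_bd.patient_id.isin(screen_positive).sum())
    checks.append(
        _binom_check("false_positive_rate", fp_count, len(non_bd),
                     config.p_false_positive_pattern)
    )
    if len(fp):
        checks.append(
            _binom_check(
                "repeat_fraction_given_fp",
                int(fp.patient_id.isin(repeat_detected).sum()),
                len(fp),
                config.p_repeat_given_positive,
            )
        )
    return CalibrationReport(checks=tuple(checks))
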