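"""File formats: event streams, patient/outcome tables, notification logs, metrics.

Event streams are JSONL (one observation per line, ISO-8601 timestamps, with
a schema-versioned header line) because EMR extracts are heterogeneous and
line-oriented parsing permits streaming; a flat CSV reader covers the same
columns. The patient table is CSV: demographics, admission window, the
reference-standard outcome and the evaluation covariates (ventilation,
analgosedation). Metrics JSON carries numerators and denominators alongside
every estimate so downstream consumers can re-derive the proportions.
"""

from __future__ import annotations

import json
import warnings
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .engine import CohortNotificationSummary
from .model import (
    AccuracyReport,
    IntervalEstimate,
    Notification,
    ObsKind,
    ObservationEvent,
    OptionalFlags,
    PatientRecord,
    PLRState,
    ReferenceOutcome,
    Sex,
    sorted_events,
    validate_record,
)
from .stats import OddsRatioResult, as_percent

EVENT_SCHEMA = "bdscreen-events/1"
NOTIFICATION_SCHEMA = "bdscreen-notifications/1"

_BOOL_KINDS = {ObsKind.VENT_CONTROLLED, ObsKind.SPONT_BREATHING, ObsKind.CPR}
_INT_KINDS = {ObsKind.RASS, ObsKind.GCS}
_PLR_KINDS = {ObsKind.PLR_LEFT, ObsKind.PLR_RIGHT}


def _fmt_time(t: datetime) -> str:
    return t.strftime("%Y-%m-%dT%H:%M")


def _parse_time(s: str, where: str) -> datetime:
    try:
        return datetime.fromisoformat(s)
    except ValueError as exc:
        raise ValueError(f"{where}: bad timestamp {s!r}") from exc


def _event_value_to_json(ev: ObservationEvent):
    if isinstance(ev.value, PLRState):
        return ev.value.value
    return ev.value


def _parse_event_value(kind: ObsKind, raw, where: str):
    if kind in _PLR_KINDS:
        try:
            return PLRState(raw)
        except ValueError as exc:
            raise ValueError(f"{where}: bad pupil state {raw!r}") from exc
    if kind in _BOOL_KINDS:
        if isinstance(raw, bool):
            return raw
        if isinstance(raw, str):
            low = raw.strip().lower()
            if low in ("true", "1", "yes"):
                return True
            if low in ("false", "0", "no"):
                return False
        if isinstance(raw, (int, float)) and raw in (0, 1):
            return bool(raw)
        raise ValueError(f"{where}: bad boolean {raw!r} for {kind.value}")
    if kind in _INT_KINDS:
        try:
            f = float(raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{where}: bad integer {raw!r} for {kind.value}") from exc
        if not f.is_integer():
            raise ValueError(f"{where}: {kind.value} must be an integer, got {raw!r}")
        return int(f)
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: bad numeric value {raw!r} for {kind.value}") from exc


def write_events(events: Iterable[ObservationEvent], path: str | Path,
                 fmt: str = "jsonl") -> None:
    path = Path(path)
    if fmt == "jsonl":
        with path.open("w") as fh:
            fh.write(json.dumps({"schema": EVENT_SCHEMA}) + "\n")
            for ev in events:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": ev.patient_id,
                            "time": _fmt_time(ev.time),
                            "kind": ev.kind.value,
                            "value": _event_value_to_json(ev),
                        }
                    )
                    + "\n"
                )
    elif fmt == "csv":
        rows = [
            {
                "patient_id": ev.patient_id,
                "time": _fmt_time(ev.time),
                "kind": ev.kind.value,
                "value": _event_value_to_json(ev),
            }
            for ev in events
        ]
        pd.DataFrame(rows, columns=["patient_id", "time", "kind", "value"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown event format {fmt!r}")


def read_events(path: str | Path, fmt: str = "jsonl") -> list[ObservationEvent]:
    """Parse an event stream; malformed lines are reported with their location."""
    path = Path(path)
    events: list[ObservationEvent] = []
    if fmt == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                where = f"{path}:{lineno}"
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{where}: malformed JSON") from exc
                if "schema" in obj:
                    if obj["schema"] != EVENT_SCHEMA:
                        raise ValueError(f"{where}: unsupported schema {obj['schema']!r}")
                    continue
                events.append(_event_from_fields(obj, where))
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=str)
        for i, row in enumerate(df.to_dict("records")):
            events.append(_event_from_fields(row, f"{path}:{i + 2}"))
    else:
        raise ValueError(f"unknown event format {fmt!r}")
    if not events:
        warnings.warn(f"{path}: no events found", stacklevel=2)
    return events


def _event_from_fields(obj: dict, where: str) -> ObservationEvent:
    for key in ("patient_id", "time", "kind", "value"):
        if key not in obj or obj[key] is None:
            raise ValueError(f"{where}: missing field {key!r}")
    try:
        kind = ObsKind(obj["kind"])
    except ValueError as exc:
        raise ValueError(f"{where}: unknown observation kind {obj['kind']!r}") from exc
    return ObservationEvent(
        patient_id=str(obj["patient_id"]),
        time=_parse_time(str(obj["time"]), where),
        kind=kind,
        value=_parse_event_value(kind, obj["value"], where),
    )


PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "admission_time", "discharge_time",
    "brain_death", "determination_time", "died_in_icu", "organ_donation",
    "ventilated", "analgosedation",
]


def write_patients(records: Sequence[PatientRecord], path: str | Path,
                   covariates: Optional[pd.DataFrame] = None) -> None:
    """Patient table CSV: demographics, admission window, outcome, covariates.

    ``covariates`` (truth log or chart review) supplies the ``ventilated`` and
    ``analgosedation`` columns used by the subgroup and odds-ratio analyses.
    """
    cov = {}
    if covariates is not None:
        cov = covariates.set_index("patient_id").to_dict("index")
    rows = []
    for r in records:
        c = cov.get(r.patient_id, {})
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex.value,
                "admission_time": _fmt_time(r.admission_time),
                "discharge_time": _fmt_time(r.discharge_time),
                "brain_death": int(r.outcome.brain_death_confirmed),
                "determination_time": (
                    _fmt_time(r.outcome.determination_time)
                    if r.outcome.determination_time
                    else ""
                ),
                "died_in_icu": int(r.outcome.died_in_icu),
                "organ_donation": int(r.outcome.organ_donation),
                "ventilated": int(bool(c.get("ventilated", False))),
                "analgosedation": int(bool(c.get("analgosedation", False))),
            }
        )
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in PATIENT_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing patient columns {missing}")
    return df


def read_records(
    events_path: str | Path,
    patients_path: str | Path,
    fmt: str = "jsonl",
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Assemble validated patient records from an event stream and patient table.

    Returns the records (each passing ``validate_record``) and the patient
    table with its evaluation covariates. Records with invariant violations
    are rejected with a message listing every violation.
    """
    events = read_events(events_path, fmt=fmt)
    patients = read_patients(patients_path)
    by_patient: dict[str, list[ObservationEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    records = []
    for row in patients.to_dict("records"):
        pid = str(row["patient_id"])
        det = row.get("determination_time")
        det_time = (
            _parse_time(str(det), f"{patients_path} patient {pid}")
            if isinstance(det, str) and det.strip()
            else None
        )
        outcome = ReferenceOutcome(
            brain_death_confirmed=bool(int(row["brain_death"])),
            determination_time=det_time,
            died_in_icu=bool(int(row.get("died_in_icu", 0) or 0)),
            organ_donation=bool(int(row.get("organ_donation", 0) or 0)),
        )
        record = PatientRecord(
            patient_id=pid,
            age=float(row["age"]),
            sex=Sex(str(row["sex"])),
            admission_time=_parse_time(str(row["admission_time"]), f"patient {pid}"),
            discharge_time=_parse_time(str(row["discharge_time"]), f"patient {pid}"),
            events=sorted_events(by_patient.get(pid, [])),
            outcome=outcome,
        )
        violations = validate_record(record)
        if violations:
            raise ValueError(
                f"{patients_path}: patient {pid} violates invariants: "
                + "; ".join(violations)
            )
        records.append(record)
    orphans = set(by_patient) - {str(r["patient_id"]) for r in patients.to_dict("records")}
    if orphans:
        raise ValueError(f"{events_path}: events for unknown patients {sorted(orphans)[:5]}")
    return records, patients


def write_notifications(log: Sequence[Notification], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(json.dumps({"schema": NOTIFICATION_SCHEMA}) + "\n")
        for n in log:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "tick_time": _fmt_time(n.tick_time),
                        "is_repeat": n.is_repeat,
                        "age": n.age,
                        "sex": n.sex.value,
                        "flags": {
                            "vent_no_spont_breathing": n.flags.vent_no_spont_breathing,
                            "icp_above_50": n.flags.icp_above_50,
                            "cpp_below_20": n.flags.cpp_below_20,
                            "sodium_above_160": n.flags.sodium_above_160,
                            "sodium_delta_gt_10": n.flags.sodium_delta_gt_10,
                            "cpr_any": n.flags.cpr_any,
                        },
                    }
                )
                + "\n"
            )


def read_notifications(path: str | Path) -> list[Notification]:
    out: list[Notification] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{where}: malformed JSON") from exc
            if "schema" in obj:
                if obj["schema"] != NOTIFICATION_SCHEMA:
                    raise ValueError(f"{where}: unsupported schema {obj['schema']!r}")
                continue
            out.append(
                Notification(
                    patient_id=str(obj["patient_id"]),
                    tick_time=_parse_time(obj["tick_time"], where),
                    is_repeat=bool(obj["is_repeat"]),
                    age=float(obj["age"]),
                    sex=Sex(obj["sex"]),
                    flags=OptionalFlags(**obj["flags"]),
                )
            )
    return out


def _interval_to_dict(est: IntervalEstimate, numerator: Optional[int],
                      denominator: Optional[int]) -> dict:
    return {
        "point": est.point,
        "percent": as_percent(est.point) if est.point is not None else None,
        "lower": est.lower,
        "upper": est.upper,
        "method": est.method,
        "confidence": est.confidence,
        "numerator": numerator,
        "denominator": denominator,
    }


def report_to_dict(report: AccuracyReport) -> dict:
    """Metrics JSON: each estimate with its bounds, method and counts."""
    m = report.matrix
    return {
        "matrix": {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn, "n": m.n},
        "n1": report.n1,
        "n0": report.n0,
        "prevalence": report.prevalence if report.n1 + report.n0 else None,
        "metrics": {
            "sensitivity": _interval_to_dict(report.sensitivity, m.tp, m.tp + m.fn),
            "specificity": _interval_to_dict(report.specificity, m.tn, m.tn + m.fp),
            "ppv": _interval_to_dict(report.ppv, m.tp, m.tp + m.fp),
            "npv": _interval_to_dict(report.npv, m.tn, m.tn + m.fn),
            "accuracy": _interval_to_dict(report.accuracy, m.tp + m.tn, m.n),
        },
    }


def odds_ratio_to_dict(result: OddsRatioResult) -> dict:
    return {
        "odds_ratio": result.odds_ratio,
        "lower": result.lower,
        "upper": result.upper,
        "confidence": result.confidence,
        "zero_cell": result.zero_cell,
    }


def format_report_table(report_dict: dict) -> str:
    """Human-readable accuracy table (percent, 95% CI) from metrics JSON."""
    lines = ["Accuracy estimates, % (95% CI)"]
    labels = {
        "sensitivity": "Sensitivity",
        "specificity": "Specificity",
        "ppv": "Positive predictive value",
        "npv": "Negative predictive value",
        "accuracy": "Overall accuracy",
    }
    for key, label in labels.items():
        m = report_dict["metrics"][key]
        if m["point"] is None:
            lines.append(f"{label:<28}undefined")
            continue
        pct = f"{as_percent(m['point']):.1f}"
        if m["lower"] is not None:
            ci = f" ({as_percent(m['lower']):.1f}-{as_percent(m['upper']):.1f})"
        else:
            ci = ""
        lines.append(f"{label:<28}{pct}{ci}")
    mx = report_dict["matrix"]
    lines.append(
        f"TP {mx['tp']}  FP {mx['fp']}  FN {mx['fn']}  TN {mx['tn']}  (N = {mx['n']})"
    )
    return "\n".join(lines)


def summary_to_dict(summary: CohortNotificationSummary) -> dict:
    return {
        "n_screen_positive": summary.n_screen_positive,
        "total_notifications": summary.total_notifications,
        "total_repeats": summary.total_repeats,
        "counts": {
            "median": summary.counts_median,
            "iqr": list(summary.counts_iqr),
            "mean": summary.counts_mean,
            "sd": summary.counts_sd,
        },
        "gaps_hours": {
            "median": summary.gaps_median_hours,
            "iqr": list(summary.gaps_iqr_hours),
            "mean": summary.gaps_mean_hours,
            "sd": summary.gaps_sd_hours,
        },
    }
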