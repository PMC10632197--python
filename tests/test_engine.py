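"""Screening-engine behaviour: the rule, the tick schedule, the log."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from bdscreen.engine import (
    evaluate_coma_criterion,
    evaluate_pupil_criterion,
    compute_optional_flags,
    latest_value,
    repeat_detected_patients,
    run_screening,
    screen_positive_patients,
    summarize_notifications,
    tick_times,
)
from bdscreen.model import (
    ComaSource,
    EngineConfig,
    ObsKind,
    PLRState,
    ReferenceOutcome,
    sorted_events,
)
from bdscreen.simulate import SimulationConfig, simulate_patient

from conftest import T0, ev, mk_record, persistent_positive_events

CFG = EngineConfig()
H12 = timedelta(hours=12)


# ---------------------------------------------------------------- oracle ----
def oracle_latest(events, kind, t, staleness):
    """Independent linear-scan reimplementation of last-value-with-staleness."""
    best = None
    for e in events:
        if e.kind is kind and e.time <= t and t - e.time <= staleness:
            if best is None or e.time >= best.time:
                best = e
    return None if best is None else best.value


def oracle_positive(events, t, cfg=CFG):
    """Brute-force evaluation of the screening rule at one tick."""
    rass = oracle_latest(events, ObsKind.RASS, t, cfg.staleness(ObsKind.RASS))
    gcs = oracle_latest(events, ObsKind.GCS, t, cfg.staleness(ObsKind.GCS))
    left = oracle_latest(events, ObsKind.PLR_LEFT, t, cfg.staleness(ObsKind.PLR_LEFT))
    right = oracle_latest(events, ObsKind.PLR_RIGHT, t, cfg.staleness(ObsKind.PLR_RIGHT))
    coma = (rass is not None and rass in (-4, -5)) or (gcs is not None and 3 <= gcs <= 6)
    plr = left == PLRState.ABSENT and right == PLRState.ABSENT
    return coma and plr


# ----------------------------------------------------------- latest_value ----
class TestLatestValue:
    def test_within_window(self):
        events = [ev("p", 11, ObsKind.RASS, -3)]
        assert latest_value(events, ObsKind.RASS, T0 + H12, H12) == -3

    def test_expired(self):
        events = [ev("p", -1, ObsKind.RASS, -3)]
        assert latest_value(events, ObsKind.RASS, T0 + H12, H12) is None

    def test_most_recent_wins(self):
        events = [ev("p", 10, ObsKind.RASS, -1), ev("p", 11, ObsKind.RASS, -4)]
        assert latest_value(events, ObsKind.RASS, T0 + H12, H12) == -4

    def test_unknown_kind_is_a_bug(self):
        with pytest.raises(KeyError):
            latest_value([], "HEART_RATE", T0, H12)


# --------------------------------------------------------------- criteria ----
class TestComaCriterion:
    @pytest.mark.parametrize(
        "events,met,source",
        [
            ([ev("p", 0, ObsKind.RASS, -5)], True, ComaSource.RASS),
            ([ev("p", 0, ObsKind.RASS, -4)], True, ComaSource.RASS),
            ([ev("p", 0, ObsKind.RASS, -3), ev("p", 0, ObsKind.GCS, 6)], True, ComaSource.GCS),
            ([ev("p", 0, ObsKind.RASS, -5), ev("p", 0, ObsKind.GCS, 3)], True, ComaSource.BOTH),
            ([ev("p", 0, ObsKind.RASS, 0), ev("p", 0, ObsKind.GCS, 7)], False, ComaSource.NONE),
            ([], False, ComaSource.NONE),  # absence never triggers
        ],
    )
    def test_rule(self, events, met, source):
        got_met, got_source = evaluate_coma_criterion(
            sorted_events(events), T0 + timedelta(hours=1), CFG
        )
        assert (got_met, got_source) == (met, source)


class TestPupilCriterion:
    @pytest.mark.parametrize(
        "left,right,met",
        [
            (PLRState.ABSENT, PLRState.ABSENT, True),
            (PLRState.ABSENT, PLRState.PRESENT, False),
            (PLRState.ABSENT, None, False),  # undocumented side fails
            (PLRState.ABSENT, PLRState.NOT_ASSESSABLE, False),
            (PLRState.NOT_ASSESSABLE, PLRState.NOT_ASSESSABLE, False),
        ],
    )
    def test_bilateral_requirement(self, left, right, met):
        events = [ev("p", 0, ObsKind.PLR_LEFT, left)]
        if right is not None:
            events.append(ev("p", 0, ObsKind.PLR_RIGHT, right))
        assert evaluate_pupil_criterion(
            sorted_events(events), T0 + timedelta(hours=1), CFG
        ) is met

    def test_stale_pupil_fails(self):
        events = [
            ev("p", 0, ObsKind.PLR_LEFT, PLRState.ABSENT),
            ev("p", 0, ObsKind.PLR_RIGHT, PLRState.ABSENT),
        ]
        assert evaluate_pupil_criterion(sorted_events(events), T0 + timedelta(hours=13), CFG) is False


class TestOptionalFlags:
    def test_sodium_threshold_and_delta(self):
        t = T0 + timedelta(hours=24)
        events = sorted_events([
            ev("p", 4, ObsKind.SODIUM, 150.0),   # t-20h
            ev("p", 23, ObsKind.SODIUM, 162.0),  # t-1h
        ])
        flags = compute_optional_flags(events, t, CFG)
        assert flags.sodium_above_160 and flags.sodium_delta_gt_10

    def test_single_sodium_value_no_delta(self):
        t = T0 + timedelta(hours=24)
        flags = compute_optional_flags(
            sorted_events([ev("p", 23, ObsKind.SODIUM, 162.0)]), t, CFG
        )
        assert flags.sodium_above_160 and not flags.sodium_delta_gt_10

    def test_icp_exactly_50_not_flagged(self):
        t = T0 + timedelta(hours=2)
        flags = compute_optional_flags(sorted_events([ev("p", 1, ObsKind.ICP, 50.0)]), t, CFG)
        assert not flags.icp_above_50

    def test_vent_without_spont_breathing(self):
        t = T0 + timedelta(hours=2)
        events = sorted_events([
            ev("p", 1, ObsKind.VENT_CONTROLLED, True),
            ev("p", 1, ObsKind.SPONT_BREATHING, False),
        ])
        assert compute_optional_flags(events, t, CFG).vent_no_spont_breathing
        # undocumented spontaneous breathing must not assert its absence
        only_vent = sorted_events([ev("p", 1, ObsKind.VENT_CONTROLLED, True)])
        assert not compute_optional_flags(only_vent, t, CFG).vent_no_spont_breathing

    def test_cpr_any_time_before_tick(self):
        t = T0 + timedelta(days=3)
        events = sorted_events([ev("p", 0, ObsKind.CPR, True)])
        assert compute_optional_flags(events, t, CFG).cpr_any


# ----------------------------------------------------------- tick schedule ----
class TestRunScreening:
    def test_continuous_positive_window_yields_five_notifications(self):
        # admitted 10:00; positives charted from day-2 05:00 to day-4 06:00
        events = persistent_positive_events("p1", 19, 67, step_h=4)
        events += [ev("p1", h, ObsKind.RASS, 0) for h in (0, 8, 16)]
        log = run_screening([mk_record(events, los_days=7)])
        times = [n.tick_time for n in log]
        assert times == [
            datetime(2020, 3, 2, 6, 0), datetime(2020, 3, 2, 18, 0),
            datetime(2020, 3, 3, 6, 0), datetime(2020, 3, 3, 18, 0),
            datetime(2020, 3, 4, 6, 0),
        ]
        assert [n.is_repeat for n in log] == [False, True, True, True, True]

    def test_never_positive_never_notifies(self):
        events = [ev("p1", h, ObsKind.RASS, 0) for h in range(0, 48, 4)]
        assert run_screening([mk_record(events)]) == []

    def test_single_positive_tick(self):
        events = persistent_positive_events("p1", 19, 19)
        log = run_screening([mk_record(events, los_days=7)])
        assert len(log) == 1 and not log[0].is_repeat

    def test_ticks_stop_at_determination(self):
        det = datetime(2020, 3, 3, 12, 0)
        outcome = ReferenceOutcome(brain_death_confirmed=True, determination_time=det)
        rec = mk_record(persistent_positive_events("p1", 4, 44), outcome=outcome)
        log = run_screening([rec])
        assert log and max(n.tick_time for n in log) <= det

    def test_duplicate_patient_id_rejected(self):
        rec = mk_record([])
        with pytest.raises(ValueError, match="more than one admission"):
            run_screening([rec, rec])

    def test_matches_brute_force_oracle_on_designed_patients(self):
        rng = np.random.default_rng(7)
        config = SimulationConfig(seed=7)
        for cls in ("brain_death", "false_positive", "true_negative"):
            rec, _ = simulate_patient(config, rng, f"x_{cls}", force_outcome=cls)
            log = run_screening([rec])
            got = {n.tick_time for n in log}
            expected = {t for t in tick_times(rec, CFG) if oracle_positive(rec.events, t)}
            assert got == expected, cls


# -------------------------------------------------------------- properties ----
class TestEngineProperties:
    def _random_record(self, rng, pid="r"):
        events = []
        for _ in range(rng.integers(10, 60)):
            h = float(rng.uniform(0, 96))
            kind = [ObsKind.RASS, ObsKind.GCS, ObsKind.PLR_LEFT, ObsKind.PLR_RIGHT][
                int(rng.integers(0, 4))
            ]
            if kind is ObsKind.RASS:
                value = int(rng.integers(-5, 5))
            elif kind is ObsKind.GCS:
                value = int(rng.integers(3, 16))
            else:
                value = [PLRState.PRESENT, PLRState.ABSENT, PLRState.NOT_ASSESSABLE][
                    int(rng.integers(0, 3))
                ]
            events.append(ev(pid, h, kind, value))
        return mk_record(events, pid=pid, los_days=4)

    def test_no_lookahead(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            rec = self._random_record(rng)
            t = tick_times(rec, CFG)[2]
            before = oracle_positive(rec.events, t)
            with_log = {n.tick_time for n in run_screening([rec])}
            # perturb the stream strictly after t
            extra = persistent_positive_events(rec.patient_id, 90, 94)
            extra = [e for e in extra if e.time > t]
            rec2 = mk_record(
                list(rec.events) + extra, pid=rec.patient_id, los_days=4
            )
            with_log2 = {n.tick_time for n in run_screening([rec2])}
            assert (t in with_log) == (t in with_log2) == before

    def test_monotone_in_deeper_coma(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            rec = self._random_record(rng)
            for t in tick_times(rec, CFG)[:4]:
                if not oracle_positive(rec.events, t):
                    continue
                deeper = mk_record(
                    list(rec.events) + [ev(rec.patient_id, (t - T0).total_seconds() / 3600,
                                           ObsKind.RASS, -5)],
                    pid=rec.patient_id, los_days=4,
                )
                assert t in {n.tick_time for n in run_screening([deeper])}

    def test_first_notification_count_equals_screen_positive_count(self, sim_cohort_414):
        *_, log = sim_cohort_414
        firsts = [n for n in log if not n.is_repeat]
        assert len(firsts) == len(screen_positive_patients(log))

    def test_gaps_are_positive_multiples_of_cadence(self, sim_cohort_414):
        *_, log = sim_cohort_414
        per_patient, _ = summarize_notifications(log)
        for s in per_patient.values():
            for gap in s.gaps_hours:
                assert gap > 0 and abs(gap / 12.0 - round(gap / 12.0)) < 1e-9


# ---------------------------------------------------------------- summary ----
class TestSummaries:
    def test_empty_log(self):
        per, cohort = summarize_notifications([])
        assert per == {} and cohort.n_screen_positive == 0
        assert cohort.total_notifications == 0 and cohort.counts_median is None

    def test_single_patient_gap_of_12h(self):
        events = persistent_positive_events("p1", 19, 31)
        log = run_screening([mk_record(events, los_days=3)])
        per, cohort = summarize_notifications(log)
        assert per["p1"].total == 2 and per["p1"].gaps_hours == (12.0,)
        assert cohort.total_repeats == 1

    def test_first_plus_repeats_equals_total(self, sim_cohort_414):
        *_, log = sim_cohort_414
        _, cohort = summarize_notifications(log)
        assert cohort.n_screen_positive + cohort.total_repeats == cohort.total_notifications

    def test_repeat_detected_needs_two_notifications(self):
        events = persistent_positive_events("p1", 19, 19)
        log = run_screening([mk_record(events)])
        assert repeat_detected_patients(log) == set()
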