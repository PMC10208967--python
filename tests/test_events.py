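"""Event-stream validation, intake arithmetic, timeseries summaries,
lick microstructure, and the operant-acquisition state machine."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from star import (
    EventRecord,
    LickCalibration,
    SessionOutcome,
    binned_rate,
    compute_intake_gkg,
    cumulative_record,
    discrimination_index,
    evaluate_acquisition,
    fit_lick_calibration,
    lick_microstructure,
    predict_intake_from_licks,
    read_event_log,
    summarize_session,
)
from star.errors import DegenerateFitError, EventValidationError, SchemaError
from star.events import debounce_licks


# ---------------------------------------------------------------- intake

@pytest.mark.parametrize(
    "volume, vv, weight, expected",
    [
        (0.0, 0.15, 25.0, 0.0),
        (1.0, 0.15, 25.0, 4.734),  # 1.0 * 0.15 * 0.789 / 0.025
        (0.5, 0.15, 30.0, 1.9725),
    ],
)
def test_intake_gkg_hand_computed(volume, vv, weight, expected):
    assert compute_intake_gkg(volume, vv, weight) == pytest.approx(expected, rel=1e-12)


def test_intake_gkg_rejects_bad_inputs():
    with pytest.raises(ValueError):
        compute_intake_gkg(1.0, 0.15, 0.0)
    with pytest.raises(ValueError):
        compute_intake_gkg(-1.0, 0.15, 25.0)
    with pytest.raises(ValueError):
        compute_intake_gkg(1.0, 1.5, 25.0)


@settings(deadline=None, derandomize=True)
@given(
    volume=st.floats(0.0, 5.0),
    weight=st.floats(15.0, 45.0),
    c=st.floats(0.1, 10.0),
)
def test_intake_gkg_linear_in_volume_inverse_in_weight(volume, weight, c):
    base = compute_intake_gkg(volume, 0.15, weight)
    assert compute_intake_gkg(c * volume, 0.15, weight) == pytest.approx(c * base, rel=1e-9)
    assert compute_intake_gkg(volume, 0.15, c * weight) == pytest.approx(base / c, rel=1e-9)


# ------------------------------------------------------------ calibration

def test_calibration_noiseless_line():
    pairs = [(n, 0.01 * n) for n in (10, 50, 100, 200)]
    cal = fit_lick_calibration(pairs)
    assert cal.slope == pytest.approx(0.01, rel=1e-12)
    assert cal.intercept == pytest.approx(0.0, abs=1e-12)
    assert cal.r == pytest.approx(1.0)
    assert cal.n_pairs == 4


def test_calibration_recovers_known_slope_within_ci():
    rng = np.random.default_rng(11)
    true_slope, true_icpt = 0.012, 0.05
    licks = rng.integers(20, 300, size=50)
    intake = true_slope * licks + true_icpt + rng.normal(0, 0.1, size=50)
    cal = fit_lick_calibration(list(zip(licks, intake)))
    lo, hi = cal.slope_ci95()
    assert lo <= true_slope <= hi


def test_calibration_preconditions():
    with pytest.raises(DegenerateFitError):
        fit_lick_calibration([(10, 0.1), (20, 0.2)])
    with pytest.raises(DegenerateFitError):
        fit_lick_calibration([(10, 0.1), (10, 0.2), (10, 0.3)])


def test_predict_intake_clips_at_zero():
    assert predict_intake_from_licks(LickCalibration(0.01, 0.0, 1.0, 5), 100) == 1.0
    assert predict_intake_from_licks(LickCalibration(0.01, -0.5, 1.0, 5), 10) == 0.0
    assert predict_intake_from_licks(LickCalibration(0.01, 0.0, 1.0, 5), 0) == 0.0


# ------------------------------------------------------- timeseries ops

def test_cumulative_record_steps_and_degenerate():
    xs, ys = cumulative_record([10, 20, 30], 60)
    assert list(xs) == [0, 10, 20, 30, 60]
    assert list(ys) == [0, 1, 2, 3, 3]
    xs0, ys0 = cumulative_record([], 60)
    assert list(ys0) == [0, 0]
    with pytest.raises(ValueError):
        cumulative_record([3, 1, 2], 60)


def test_cumulative_record_count_conservation():
    rng = np.random.default_rng(3)
    times = np.sort(rng.uniform(0, 3600, 500))
    _, ys = cumulative_record(times, 3600)
    assert ys[-1] == 500
    assert np.all(np.diff(ys) >= 0)


def test_binned_rate_boundary_rule():
    assert list(binned_rate([0.5, 9.9, 10.0], 10, 20)) == [2, 1]


def test_binned_rate_session_end_in_last_bin():
    assert list(binned_rate([20.0], 10, 20)) == [0, 1]


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 3600), max_size=200), st.sampled_from([1.0, 10.0, 60.0]))
def test_binned_rate_conservation(times, bin_s):
    counts = binned_rate(sorted(times), bin_s, 3600)
    assert counts.sum() == len(times)


def test_rebinning_consistency():
    rng = np.random.default_rng(4)
    times = np.sort(rng.uniform(0, 3600, 1000))
    fine = binned_rate(times, 1.0, 3600)
    coarse = binned_rate(times, 10.0, 3600)
    assert np.array_equal(fine.reshape(-1, 10).sum(axis=1), coarse)


def test_discrimination_index():
    assert discrimination_index(70, 30) == pytest.approx(0.70)
    assert discrimination_index(5, 0) == 1.0
    assert math.isnan(discrimination_index(0, 0))


# ---------------------------------------------------------- microstructure

def test_microstructure_burst_partition_example():
    ms = lick_microstructure([0, 0.1, 0.2, 1.0, 1.1], 0.5)
    assert ms.n_bursts == 2
    assert list(ms.burst_sizes) == [3, 2]
    assert ms.n_licks == 5


def test_microstructure_single_lick():
    ms = lick_microstructure([42.0], 0.5)
    assert (ms.n_bursts, ms.n_licks) == (1, 1)


def test_microstructure_recovers_generated_bursts():
    rng = np.random.default_rng(5)
    t, times = 0.0, []
    for _ in range(20):
        for _ in range(rng.integers(3, 15)):
            times.append(t)
            t += 0.12
        t += 5.0
    ms = lick_microstructure(times, 0.5)
    assert ms.n_bursts == 20
    assert ms.burst_sizes.sum() == len(times)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 100), min_size=1, max_size=100))
def test_microstructure_partition_invariants(raw):
    times = np.sort(np.asarray(raw))
    ms = lick_microstructure(times, 0.5)
    assert ms.burst_sizes.sum() == ms.n_licks == times.size
    # every between-burst gap exceeds the threshold
    edges = np.cumsum(ms.burst_sizes)[:-1]
    for e in edges:
        assert times[e] - times[e - 1] > 0.5


def test_debounce_collapses_chatter():
    t = np.array([0.0, 0.005, 0.010, 0.100, 0.105, 0.500])
    assert list(debounce_licks(t, 0.020)) == [0.0, 0.100, 0.500]


# ----------------------------------------------------------- acquisition

def S(cap, di=None):
    return SessionOutcome(licks=100 if cap else 40, cap_reached=cap, discrimination_index=di)


FAST_TRACK = [S(True)] + [S(True)] * 4 + [S(True, 0.8), S(True, 0.8)]

ACQUISITION_CASES = [
    # (sessions, status, sessions_to_acquire, reverts, final phases checked)
    (FAST_TRACK, "acquired", 7, 0),
    # empty input
    ([], "in_progress", None, 0),
    # magazine not yet passed
    ([S(False), S(False)], "in_progress", None, 0),
    # magazine failures never accrue reverts
    ([S(False)] * 9, "in_progress", None, 0),
    # single cap day in criteria1 is not enough
    ([S(True), S(True)], "in_progress", None, 0),
    # non-consecutive successes do not advance
    ([S(True), S(True), S(False), S(True), S(False)], "in_progress", None, 0),
    # three consecutive failures in criteria1 revert to magazine
    ([S(True), S(False), S(False), S(False)], "in_progress", None, 1),
    # three failures in criteria2 revert to criteria1
    ([S(True), S(True), S(True), S(False), S(False), S(False)], "in_progress", None, 1),
    # revert then re-advance then acquire
    (
        [S(True), S(True), S(True), S(False), S(False), S(False),
         S(True), S(True), S(True), S(True), S(True, 0.9), S(True, 0.9)],
        "acquired", 12, 1,
    ),
    # discrimination: cap alone is not acquisition
    ([*FAST_TRACK[:5], S(True, 0.5), S(True, 0.5)], "in_progress", None, 0),
    # discrimination: DI alone (no cap) is not acquisition
    ([*FAST_TRACK[:5], S(False, 0.9), S(False, 0.9), S(False, 0.9)], "in_progress", None, 1),
    # undefined DI (no responses) counts as a failed session
    ([*FAST_TRACK[:5], S(True, float("nan"))] * 1 + [S(False)] * 2, "in_progress", None, 1),
    # three total reverts remove the animal
    (
        [S(True)] + ([S(True), S(True), S(False), S(False), S(False)]) * 3,
        "removed", None, 3,
    ),
    # exactly at the 70% criterion counts as success
    ([*FAST_TRACK[:5], S(True, 0.70), S(True, 0.70)], "acquired", 7, 0),
]


@pytest.mark.parametrize("sessions, status, n_acq, reverts", ACQUISITION_CASES)
def test_acquisition_state_machine_hand_traces(sessions, status, n_acq, reverts):
    out = evaluate_acquisition(sessions)
    assert out.status == status
    assert out.sessions_to_acquire == n_acq
    assert out.reverts_used == reverts
    assert len(out.phase_trajectory) == len(sessions)


def test_acquisition_trajectory_phases():
    out = evaluate_acquisition(FAST_TRACK)
    assert out.phase_trajectory == [
        "magazine", "criteria1", "criteria1", "criteria2", "criteria2",
        "discrimination", "discrimination",
    ]


def test_acquisition_revert_resets_success_window():
    # after reverting from criteria2, one cap day in criteria1 must not advance
    sessions = [S(True), S(True), S(True), S(False), S(False), S(False), S(True)]
    out = evaluate_acquisition(sessions)
    assert out.phase_trajectory[-1] == "criteria1"
    assert out.status == "in_progress"


# ------------------------------------------------------------- event log IO

LOG = """subject,session,time_s,kind
m1,d1,1.0,active_poke
m1,d1,2.0,lick
m1,d1,2.5,lick
"""


def test_read_event_log_basic():
    recs = read_event_log(io.StringIO(LOG))
    assert len(recs) == 1
    rec = recs[0]
    assert len(rec.events) == 3
    assert [t for t, _ in rec.events] == [1.0, 2.0, 2.5]


def test_read_event_log_empty_with_header():
    assert read_event_log(io.StringIO("subject,session,time_s,kind\n")) == []


def test_read_event_log_out_of_bounds():
    log = "subject,session,time_s,kind\nm1,d1,3601,lick\n"
    with pytest.raises(EventValidationError):
        read_event_log(io.StringIO(log), duration_s=3600)


def test_read_event_log_missing_column():
    with pytest.raises(SchemaError):
        read_event_log(io.StringIO("subject,session,time_s\nm1,d1,1.0\n"))


def test_read_event_log_reports_malformed_lines():
    log = "subject,session,time_s,kind\nm1,d1,oops,lick\nm1,d1,2.0,lick\n"
    with pytest.warns(UserWarning, match=r"lines \[2\]"):
        recs = read_event_log(io.StringIO(log))
    assert len(recs[0].events) == 1


def test_sipper_alternation_enforced():
    with pytest.raises(EventValidationError):
        EventRecord("m1", "d1", [(1.0, "sipper_retract")])
    with pytest.raises(EventValidationError):
        EventRecord("m1", "d1", [(1.0, "sipper_extend"), (2.0, "sipper_extend")])


def test_summarize_session_counts_and_dry_rule():
    events = (
        [(float(i), "active_poke") for i in range(30)]
        + [(100.0, "sipper_extend"), (110.0, "sipper_retract")]
        + [(200.0, "sipper_extend"), (210.0, "sipper_retract")]
        + [(300.0, "sipper_extend"), (310.0, "sipper_retract")]
        + [(100.0 + 0.1 * i, "lick") for i in range(120)]
    )
    rec = EventRecord("m1", "d1", sorted(events))
    s = summarize_session(
        rec, epoch="phenotyping", condition="alcohol_only", session_index=1,
        consumed_volume_mL=0.3, weight_g=28.0,
    )
    assert (s.active_responses, s.reinforcers, s.licks) == (30, 3, 120)
    assert s.intake_gkg > 0
    dry = summarize_session(
        rec, epoch="conditioned_reinforcement", condition="dry", session_index=1,
        consumed_volume_mL=0.0, weight_g=28.0,
    )
    assert dry.intake_gkg == 0.0
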