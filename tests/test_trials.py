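"""Shuttle detection, avoidance/escape classification and endpoints."""

import numpy as np
import pandas as pd
import pytest

from shuttlekit.session_io import EventLog, Geometry, Session, TrackingSeries
from shuttlekit.trials import (Trial, TrialValidationError, avoidance_rate,
                               classify_trials, detect_shuttles,
                               exclusion_check, max_velocity_event,
                               session_behavior, shuttle_initiate)

FR = 30.0


def _session_from_x(x):
    arr = np.column_stack([np.asarray(x, float), np.zeros(len(x))])
    ts = TrackingSeries(FR, 0.0, arr.copy(), arr.copy())
    ev = EventLog(pd.DataFrame(columns=["kind", "onset_s", "offset_s", "trial"]))
    return Session(ts, ev, geometry=Geometry())


def _events(rows):
    return EventLog(pd.DataFrame(rows, columns=["kind", "onset_s", "offset_s", "trial"]))


# ---------------------------------------------------------------------------
# crossings
# ---------------------------------------------------------------------------

def test_single_monotone_traverse_one_crossing():
    x = np.linspace(50, 310, 120)
    times, dirs = detect_shuttles(_session_from_x(x))
    assert len(times) == 1 and dirs[0] == 1
    # crossing registered at the first sample past the hurdle
    i = int(round(times[0] * FR))
    assert x[i - 1] < 180 <= x[i]


def test_jitter_inside_band_no_crossings():
    rng = np.random.default_rng(0)
    x = 180 + rng.uniform(-5, 5, 600)
    times, _ = detect_shuttles(_session_from_x(x))
    assert len(times) == 0


def test_two_traverses_alternate_direction():
    x = np.concatenate([np.linspace(60, 300, 100), np.linspace(300, 60, 100)])
    times, dirs = detect_shuttles(_session_from_x(x))
    assert list(dirs) == [1, -1]


def test_band_excursion_without_crossing_not_counted():
    # approach into the band from the left, retreat, then full traverse
    x = np.concatenate([np.linspace(60, 175, 60), np.linspace(175, 60, 60),
                        np.linspace(60, 310, 80)])
    times, dirs = detect_shuttles(_session_from_x(x))
    assert list(dirs) == [1] and len(times) == 1


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_avoidance_latency():
    events = _events([("WS", 10.0, 13.2, 0)])
    trials = classify_trials(events, np.array([13.2]), ws_max=15.0)
    t = trials[0]
    assert t.outcome == "avoidance"
    assert t.latency_avoid_s == pytest.approx(3.2)
    assert t.latency_escape_s is None


def test_escape_latency():
    events = _events([("WS", 10.0, 25.0, 0), ("US", 25.0, 25.8, 0)])
    trials = classify_trials(events, np.array([25.8]), ws_max=15.0)
    t = trials[0]
    assert t.outcome == "escape"
    assert t.latency_escape_s == pytest.approx(0.8)
    assert t.us_onset_s == pytest.approx(25.0)


def test_iti_only_crossing_flags_invalid():
    events = _events([("WS", 10.0, 25.0, 0)])
    trials = classify_trials(events, np.array([40.0]), ws_max=15.0)
    assert trials[0].outcome == "invalid"


def test_us_without_crossing_is_validation_error():
    events = _events([("WS", 10.0, 25.0, 0), ("US", 25.0, 40.0, 0)])
    with pytest.raises(TrialValidationError):
        classify_trials(events, np.array([]), ws_max=15.0)


@pytest.mark.parametrize("n_avoid, n_total, expected",
                         [(24, 30, 80.0), (0, 30, 0.0), (30, 30, 100.0)])
def test_avoidance_rate(n_avoid, n_total, expected):
    trials = [Trial(i, 0, 1, outcome="avoidance" if i < n_avoid else "escape")
              for i in range(n_total)]
    assert avoidance_rate(trials) == pytest.approx(expected)


def test_avoidance_rate_empty_errors():
    with pytest.raises(ValueError):
        avoidance_rate([])


@pytest.mark.parametrize("rates, decision", [
    ([5, 10, 20, 25, 29], "exclude"),
    ([5, 10, 20, 25, 30], "include"),
    ([40.0], "include"),
    ([5, 10], "pending"),
])
def test_exclusion_rule(rates, decision):
    assert exclusion_check(rates) == decision


# ---------------------------------------------------------------------------
# event timing
# ---------------------------------------------------------------------------

def test_shuttle_initiate_backtracks_to_movement_onset():
    # immobile until t=2.0 s, then 4 mm/frame rightwards: crosses 180 at 3.0 s
    n = int(6.0 * FR)
    x = np.full(n, 60.0)
    i0 = int(2.0 * FR)
    x[i0:] = np.minimum(60.0 + 4.0 * np.arange(1, n - i0 + 1), 330.0)
    ses = _session_from_x(x)
    times, _ = detect_shuttles(ses)
    assert times[0] == pytest.approx(3.0, abs=1 / FR)
    t = shuttle_initiate(ses.tracking, float(times[0]), thr=1.0)
    assert t == pytest.approx(2.0, abs=2 / FR)


def test_shuttle_initiate_motion_from_start_warns_and_clamps():
    x = np.linspace(0, 350, 150)
    ses = _session_from_x(x)
    times, _ = detect_shuttles(ses)
    t = shuttle_initiate(ses.tracking, float(times[0]), thr=1.0)
    assert t == pytest.approx(0.0, abs=1 / FR)


def test_shuttle_initiate_uses_run_containing_crossing():
    # two motion runs separated by immobility; crossing is in the second
    n = int(8 * FR)
    x = np.full(n, 60.0)
    x[30:60] = 60 + np.linspace(0, 50, 30)      # early run, no crossing
    x[60:150] = 110.0                           # immobile
    x[150:] = np.linspace(110, 330, n - 150)    # crossing run
    ses = _session_from_x(x)
    times, _ = detect_shuttles(ses)
    t = shuttle_initiate(ses.tracking, float(times[0]), thr=1.0)
    assert t == pytest.approx(150 / FR, abs=2 / FR)


def test_max_velocity_triangular_peak():
    n = int(10 * FR)
    speed_peak_frame = int(5.0 * FR)
    steps = np.concatenate([np.linspace(0, 10, speed_peak_frame),
                            np.linspace(10, 0, n - speed_peak_frame)])
    x = 10.0 + np.cumsum(steps) * 0.01
    ses = _session_from_x(x)
    t = max_velocity_event(ses.tracking, (3.0, 8.0))
    assert t == pytest.approx(5.0, abs=3 / FR)


def test_max_velocity_constant_speed_ties_to_window_start():
    x = np.arange(0, 300.0) * 0.5
    ses = _session_from_x(x)
    t = max_velocity_event(ses.tracking, (2.0, 6.0))
    assert t == pytest.approx(2.0, abs=1 / FR)


def test_max_velocity_ignores_peak_outside_window():
    n = int(10 * FR)
    steps = np.ones(n) * 0.2
    steps[int(8.5 * FR):int(9 * FR)] = 10.0  # big peak after the window
    steps[int(4 * FR):int(4.2 * FR)] = 2.0   # modest in-window peak
    x = np.cumsum(steps)
    ses = _session_from_x(x)
    t = max_velocity_event(ses.tracking, (2.0, 6.0))
    assert 3.8 <= t <= 4.4


def test_max_velocity_empty_window_errors():
    ses = _session_from_x(np.zeros(60))
    with pytest.raises(ValueError):
        max_velocity_event(ses.tracking, (100.0, 105.0))


# ---------------------------------------------------------------------------
# ground-truth recovery
# ---------------------------------------------------------------------------

def test_outcomes_and_latencies_recovered(full_session):
    cfg, session, gt = full_session
    times, _ = detect_shuttles(session)
    trials = classify_trials(session.events, times, ws_max=cfg.ws_max_dur)
    assert [t.outcome for t in trials] == gt.trial_outcomes
    err = [abs(t.shuttle_s - s) for t, s in zip(trials, gt.shuttle_times)]
    assert max(err) <= 1.0 / cfg.frame_rate + 1e-9
    rate = avoidance_rate(trials)
    escape_pct = 100.0 * sum(t.outcome == "escape" for t in trials) / len(trials)
    assert rate + escape_pct == pytest.approx(100.0)


def test_event_ordering_on_avoidance_trials(full_session):
    """Initiate <= max velocity <= shuttle for avoidance trials."""
    from shuttlekit.freezing import detect_freezing
    from shuttlekit.trials import annotate_trials
    cfg, session, gt = full_session
    thr = detect_freezing(session.tracking).threshold
    times, _ = detect_shuttles(session)
    trials = classify_trials(session.events, times, ws_max=cfg.ws_max_dur)
    annotate_trials(session, trials, thr)
    checked = 0
    for t in trials:
        if t.outcome != "avoidance":
            continue
        assert t.shuttle_initiate_s <= t.max_velocity_s + 1e-9
        assert t.max_velocity_s <= t.shuttle_s + 1e-9
        checked += 1
    assert checked >= 10


def test_session_behavior_summary(full_session):
    cfg, session, gt = full_session
    times, _ = detect_shuttles(session)
    trials = classify_trials(session.events, times, ws_max=cfg.ws_max_dur)
    summary = session_behavior(trials)
    assert summary["n_trials"] == cfg.n_trials
    assert 0.0 <= summary["avoidance_rate_pct"] <= 100.0
    assert summary["mean_latency_escape_s"] < summary["mean_latency_avoid_s"]
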