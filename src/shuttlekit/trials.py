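"""Trial segmentation, shuttle detection and behavioral endpoints.

In signaled two-way active avoidance, each trial opens with a warning
signal (WS, up to 15 s). Shuttling over the hurdle during the WS terminates
it and prevents the footshock (avoidance trial); failing to shuttle brings
the footshock (US) on until the animal crosses (escape trial). Behavioral
endpoints per trial: the crossing time (Shuttle), the onset of the movement
run that produced it (Shuttle Initiate), the moment of highest movement
velocity during the WS (Max Velocity), and outcome-specific latencies —
latency to avoid = shuttle - WS onset, latency to escape = shuttle - US
onset. The session endpoint is the avoidance rate, 100 x n_avoid / n_trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .session_io import EventLog, Session, TrackingSeries

logger = logging.getLogger(__name__)

HYSTERESIS_MM = 10.0          # half-width of the dead band around the hurdle
SPEED_SMOOTH_FRAMES = 5       # centered moving average for Max Velocity


class TrialValidationError(ValueError):
    pass


@dataclass
class Trial:
    index: int
    ws_onset_s: float
    ws_offset_s: float
    us_onset_s: Optional[float] = None
    us_offset_s: Optional[float] = None
    outcome: str = "invalid"  # avoidance | escape | invalid
    shuttle_s: Optional[float] = None
    shuttle_initiate_s: Optional[float] = None
    max_velocity_s: Optional[float] = None
    latency_avoid_s: Optional[float] = None
    latency_escape_s: Optional[float] = None


def detect_shuttles(session: Session) -> tuple[np.ndarray, np.ndarray]:
    """Hurdle-crossing times from the body-center x trajectory.

    A crossing is registered at the first sample on the far side of the
    hurdle after the animal has been beyond a +/-10 mm hysteresis band on
    the near side; jitter inside the band never counts, and consecutive
    same-direction crossings are suppressed by the arming logic itself.
    Returns (times, directions) with direction +1 for left-to-right.
    """
    if session.geometry is None:
        raise ValueError("session has no geometry; cannot detect crossings")
    hurdle = session.geometry.hurdle_pos
    x = session.tracking.center[:, 0]
    t = session.tracking.times
    lo, hi = hurdle - HYSTERESIS_MM, hurdle + HYSTERESIS_MM

    times, directions = [], []
    finite = np.isfinite(x)
    if not finite.any():
        return np.empty(0), np.empty(0, dtype=int)
    armed = 0  # -1: animal has been left of the band; +1: right of it
    for i in range(int(np.argmax(finite)), x.size):
        xi = x[i]
        if not np.isfinite(xi):
            continue
        if armed == -1 and xi >= hurdle:
            times.append(t[i])
            directions.append(1)
            armed = 0
        elif armed == 1 and xi <= hurdle:
            times.append(t[i])
            directions.append(-1)
            armed = 0
        if xi < lo:
            armed = -1
        elif xi > hi:
            armed = 1
    return np.asarray(times), np.asarray(directions, dtype=int)


def classify_trials(events: EventLog, crossings: np.ndarray,
                    ws_max: float = 15.0) -> list[Trial]:
    """Label each WS presentation avoidance or escape from crossing times.

    First crossing in (ws_onset, ws_onset + ws_max] with no US: avoidance.
    First crossing after US onset: escape. A trial with a US but no
    subsequent crossing is a validation error (escape is obligatory: the
    shock stays on until the animal crosses).
    """
    crossings = np.sort(np.asarray(crossings, dtype=float))
    ws = events.of_kind("WS")
    us = events.of_kind("US")
    out: list[Trial] = []
    for i, row in ws.iterrows():
        trial = Trial(index=int(row.get("trial", i)),
                      ws_onset_s=float(row["onset_s"]),
                      ws_offset_s=float(row["offset_s"]))
        us_rows = us[(us["onset_s"] >= trial.ws_onset_s) &
                     (us["onset_s"] <= trial.ws_onset_s + ws_max + 1e-9)]
        if len(us_rows):
            trial.us_onset_s = float(us_rows.iloc[0]["onset_s"])
            trial.us_offset_s = float(us_rows.iloc[0]["offset_s"])
            after = crossings[crossings > trial.us_onset_s]
            if after.size == 0:
                raise TrialValidationError(
                    f"trial {trial.index}: US at {trial.us_onset_s:.2f}s with no "
                    "subsequent crossing")
            trial.outcome = "escape"
            trial.shuttle_s = float(after[0])
            trial.latency_escape_s = trial.shuttle_s - trial.us_onset_s
        else:
            inside = crossings[(crossings > trial.ws_onset_s) &
                               (crossings <= trial.ws_onset_s + ws_max + 1e-9)]
            if inside.size == 0:
                logger.warning("trial %d: no US and no crossing during the WS; "
                               "flagged invalid", trial.index)
                trial.outcome = "invalid"
            else:
                trial.outcome = "avoidance"
                trial.shuttle_s = float(inside[0])
                trial.latency_avoid_s = trial.shuttle_s - trial.ws_onset_s
        out.append(trial)
    return out


def avoidance_rate(trials: list[Trial]) -> float:
    """Percentage of avoidance trials over all trials."""
    if not trials:
        raise ValueError("avoidance_rate needs at least one trial")
    n_avoid = sum(1 for t in trials if t.outcome == "avoidance")
    return 100.0 * n_avoid / len(trials)


def exclusion_check(daily_rates: list[float], threshold: float = 30.0,
                    day: int = 5) -> str:
    """Subject-inclusion rule: exclude if no session up to ``day`` reaches
    ``threshold`` % avoidance. With fewer sessions than ``day`` the decision
    is deferred ("pending") unless the threshold was already reached."""
    considered = daily_rates[:day]
    if any(r >= threshold for r in considered):
        return "include"
    if len(daily_rates) < day:
        logger.warning("only %d of %d sessions available; exclusion decision deferred",
                       len(daily_rates), day)
        return "pending"
    return "exclude"


def _smoothed_speed(tracking: TrackingSeries) -> np.ndarray:
    """Body-center speed (mm/s), centered moving average over 5 frames.

    Element i is aligned with displacement i (between frames i and i+1).
    """
    dx = np.diff(tracking.center, axis=0)
    speed = np.hypot(dx[:, 0], dx[:, 1]) * tracking.frame_rate
    k = SPEED_SMOOTH_FRAMES
    if speed.size < k:
        return speed
    kernel = np.ones(k) / k
    sm = np.convolve(speed, kernel, mode="same")
    return sm


def shuttle_initiate(tracking: TrackingSeries, shuttle_s: float,
                     thr: float) -> float:
    """Onset of the movement run that culminates in the crossing.

    Backtracks from the crossing through consecutive frames whose
    body-center displacement exceeds the session movement threshold; the
    run starts at the first frame after the last immobile (<= thr) frame.
    """
    dx = np.diff(tracking.center, axis=0)
    disp = np.hypot(dx[:, 0], dx[:, 1])
    fr = tracking.frame_rate
    i_cross = int(round((shuttle_s - tracking.start_offset) * fr))
    i_cross = min(max(i_cross, 0), disp.size - 1)
    # displacement j covers the step into frame j+1; the step that produced
    # the crossing sample is disp[i_cross - 1]
    j = max(i_cross - 1, 0)
    if disp[j] <= thr or not np.isfinite(disp[j]):
        logger.warning("no above-threshold movement run contains the crossing "
                       "at %.3f s; returning crossing time", shuttle_s)
        return shuttle_s
    while j > 0 and np.isfinite(disp[j - 1]) and disp[j - 1] > thr:
        j -= 1
    if j == 0:
        logger.warning("movement run reaches the start of the series; "
                       "initiate clamped to the first frame")
    return tracking.start_offset + j / fr


def max_velocity_event(tracking: TrackingSeries,
                       ws_interval: tuple[float, float]) -> float:
    """Time of highest smoothed body-center speed within the WS window.

    Ties break to the earliest frame.
    """
    on, off = ws_interval
    speed = _smoothed_speed(tracking)
    t = tracking.start_offset + np.arange(speed.size) / tracking.frame_rate
    mask = (t >= on) & (t < off)
    if not mask.any():
        raise ValueError(f"empty WS window ({on}, {off}) for this tracking series")
    seg = np.where(mask, speed, -np.inf)
    seg[~np.isfinite(speed)] = -np.inf
    i = int(np.argmax(seg))  # np.argmax returns the earliest maximum
    return float(t[i])


def annotate_trials(session: Session, trials: list[Trial], thr: float) -> list[Trial]:
    """Fill shuttle-initiate and max-velocity event times in place."""
    for trial in trials:
        if trial.shuttle_s is not None:
            trial.shuttle_initiate_s = shuttle_initiate(session.tracking,
                                                        trial.shuttle_s, thr)
        try:
            trial.max_velocity_s = max_velocity_event(
                session.tracking, (trial.ws_onset_s, trial.ws_offset_s))
        except ValueError:
            trial.max_velocity_s = None
    return trials


def session_behavior(trials: list[Trial], freezing_summary: dict | None = None) -> dict:
    """Session-level behavioral summary (rates, mean latencies, freezing)."""
    valid = [t for t in trials if t.outcome in ("avoidance", "escape")]
    avoid = [t for t in trials if t.outcome == "avoidance"]
    escape = [t for t in trials if t.outcome == "escape"]
    summary = {
        "n_trials": len(trials),
        "n_avoidance": len(avoid),
        "n_escape": len(escape),
        "avoidance_rate_pct": avoidance_rate(trials) if trials else float("nan"),
        "mean_latency_avoid_s": float(np.mean([t.latency_avoid_s for t in avoid]))
        if avoid else None,
        "mean_latency_escape_s": float(np.mean([t.latency_escape_s for t in escape]))
        if escape else None,
    }
    if len(valid) != len(trials):
        summary["n_invalid"] = len(trials) - len(valid)
    if freezing_summary:
        summary.update(freezing_summary)
    return summary
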