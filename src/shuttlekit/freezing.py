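"""Freeze detection from pose tracking.

The detector follows a fixed pipeline:

1. frame-by-frame Euclidean displacement of nose and body center,
2. a single session-level movement threshold: the 40% quantile of the
   pooled nose + body-center displacements (linear-interpolation quantile
   convention at h = (n-1)q),
3. a binary coincident-immobility vector — frame i is 1 iff *both* body
   parts moved <= threshold (the comparison is inclusive),
4. penalized mean-shift changepoint segmentation of that vector with a
   minimum segment length of 30 video frames,
5. candidate bouts = maximal runs of consecutive segments whose mean
   immobility exceeds 0.5,
6. truncation of a bout at the first movement run strictly longer than
   5 consecutive frames inside it,
7. a >= 1 s duration filter; surviving bouts are freezing,
8. context assignment (WS vs ITI) by the bout's onset time.

Quantities are frames internally and seconds at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import changepoint
from .session_io import EventLog, TrackingSeries

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.40
DEFAULT_MIN_SEG = 30
DEFAULT_TRUNCATION_RUN = 5
DEFAULT_MIN_BOUT_S = 1.0


@dataclass
class ImmobilityVector:
    """Binary coincident non-movement series (1 entry per frame pair)."""

    values: np.ndarray
    frame_rate: float
    threshold_used: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("immobility vector must be binary")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ChangepointResult:
    boundaries: list[int]
    segment_means: np.ndarray
    penalty: float
    method: str = "pelt"


@dataclass
class FreezeBout:
    start_s: float
    end_s: float
    truncated: bool = False
    context: str = "other"  # WS | ITI | other

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def frame_distances(ts: TrackingSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Euclidean displacement (mm) of nose and body center.

    Distances spanning a missing frame are NaN. Returns empty arrays for
    series with fewer than two frames.
    """
    if len(ts) < 2:
        return np.empty(0), np.empty(0)
    d_nose = np.hypot(*np.diff(ts.nose, axis=0).T)
    d_center = np.hypot(*np.diff(ts.center, axis=0).T)
    return d_nose, d_center


def movement_threshold(dist_nose: np.ndarray, dist_center: np.ndarray,
                       q: float = DEFAULT_QUANTILE) -> float:
    """Session movement threshold: q-quantile of the pooled displacements."""
    pooled = np.concatenate([np.asarray(dist_nose, float).ravel(),
                             np.asarray(dist_center, float).ravel()])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no finite displacement values to compute a threshold from")
    return float(np.quantile(pooled, q))  # numpy default = linear interpolation


def immobility_vector(dist_nose: np.ndarray, dist_center: np.ndarray,
                      thr: float, frame_rate: float = 30.0) -> ImmobilityVector:
    """1 where nose AND body center both moved <= ``thr`` mm (inclusive)."""
    dn = np.asarray(dist_nose, float)
    dc = np.asarray(dist_center, float)
    if dn.shape != dc.shape:
        raise ValueError(f"distance series lengths differ: {dn.shape} vs {dc.shape}")
    v = ((dn <= thr) & (dc <= thr)).astype(int)
    return ImmobilityVector(v, frame_rate, thr)


def detect_changepoints(v: ImmobilityVector, min_seg: int = DEFAULT_MIN_SEG,
                        penalty: float | None = None,
                        method: str = "pelt") -> ChangepointResult:
    """Segment the immobility vector into constant-mean regimes.

    Gaussian fixed-variance mean-shift cost with an MBIC-magnitude penalty
    (see :mod:`shuttlekit.changepoint`); every segment >= ``min_seg`` frames.
    """
    x = v.values.astype(float)
    if x.size < 2 * min_seg:
        logger.warning("series of %d frames is too short for min_seg=%d; "
                       "no changepoints", x.size, min_seg)
        return ChangepointResult([], changepoint.segment_means(x, []) if x.size else
                                 np.empty(0), 0.0, method)
    pen = changepoint.mbic_penalty(x.size) if penalty is None else penalty
    solver = {"pelt": changepoint.pelt, "exact": changepoint.exact_segmentation}[method]
    cps = solver(x, penalty=pen, min_seg=min_seg)
    return ChangepointResult(cps, changepoint.segment_means(x, cps), pen, method)


def extract_bouts(cp: ChangepointResult, v: ImmobilityVector,
                  mean_rule: float = 0.5) -> list[tuple[int, int]]:
    """Candidate immobility intervals: maximal runs of segments whose mean
    immobility exceeds ``mean_rule``, as half-open frame intervals."""
    bounds = [0, *cp.boundaries, len(v)]
    immobile = cp.segment_means > mean_rule
    bouts: list[tuple[int, int]] = []
    for i, flag in enumerate(immobile):
        if not flag:
            continue
        start, stop = bounds[i], bounds[i + 1]
        if bouts and bouts[-1][1] == start:
            bouts[-1] = (bouts[-1][0], stop)  # merge adjacent immobile segments
        else:
            bouts.append((start, stop))
    return bouts


def truncate_bout(bout: tuple[int, int], v: ImmobilityVector,
                  k: int = DEFAULT_TRUNCATION_RUN) -> tuple[tuple[int, int], bool]:
    """Cut a bout at the first movement run strictly longer than ``k`` frames.

    Returns the (possibly shortened) bout and a flag saying whether the
    truncation rule fired.
    """
    start, stop = bout
    seg = v.values[start:stop]
    moving = seg == 0
    run = 0
    for i, m in enumerate(moving):
        run = run + 1 if m else 0
        if run > k:
            cut = start + i - run + 1  # first frame of the offending run
            return (start, cut), True
    return bout, False


def filter_bouts(bouts: list[tuple[tuple[int, int], bool]], frame_rate: float,
                 min_dur: float = DEFAULT_MIN_BOUT_S,
                 t0: float = 0.0) -> list[FreezeBout]:
    """Keep bouts lasting >= ``min_dur`` seconds and convert to seconds.

    ``t0`` is the session time of the tracking series' first frame; the
    immobility sample i spans frames [i, i+1], so bout endpoints map to
    t0 + frame / frame_rate.
    """
    out = []
    for (start, stop), truncated in bouts:
        dur = (stop - start) / frame_rate
        if dur + 1e-12 >= min_dur:
            out.append(FreezeBout(t0 + start / frame_rate,
                                  t0 + stop / frame_rate, truncated))
    return out


def classify_freezing(bouts: list[FreezeBout], events: EventLog) -> dict:
    """Assign WS/ITI context by bout onset and summarise per session.

    A bout belongs to the WS if its onset falls inside a WS interval; to the
    ITI if its onset falls between a trial's WS/US end and the next trial's
    WS onset (or inside a TRIAL interval outside the WS); otherwise "other".
    Summaries are the total and per-trial mean freezing seconds per context.
    """
    ws = events.of_kind("WS")
    trials = events.of_kind("TRIAL")
    for bout in bouts:
        t = bout.start_s
        if ((ws["onset_s"] <= t) & (t < ws["offset_s"])).any():
            bout.context = "WS"
        elif len(trials) and ((trials["onset_s"] <= t) & (t < trials["offset_s"])).any():
            bout.context = "ITI"
        else:
            bout.context = "other"
    n_trials = max(len(ws), 1)
    ws_total = sum(b.duration_s for b in bouts if b.context == "WS")
    iti_total = sum(b.duration_s for b in bouts if b.context == "ITI")
    return {
        "ws_freezing_s": ws_total,
        "iti_freezing_s": iti_total,
        "ws_freezing_per_trial_s": ws_total / n_trials,
        "iti_freezing_per_trial_s": iti_total / n_trials,
        "n_bouts": len(bouts),
    }


@dataclass
class FreezingResult:
    threshold: float
    vector: ImmobilityVector
    changepoints: ChangepointResult
    bouts: list[FreezeBout]
    summary: dict = field(default_factory=dict)


def detect_freezing(ts: TrackingSeries, events: EventLog | None = None,
                    q: float = DEFAULT_QUANTILE, min_seg: int = DEFAULT_MIN_SEG,
                    penalty: float | None = None,
                    truncation_run: int = DEFAULT_TRUNCATION_RUN,
                    min_dur: float = DEFAULT_MIN_BOUT_S) -> FreezingResult:
    """Run the full freeze-detection pipeline on a tracking series."""
    d_nose, d_center = frame_distances(ts)
    thr = movement_threshold(d_nose, d_center, q)
    v = immobility_vector(d_nose, d_center, thr, ts.frame_rate)
    cp = detect_changepoints(v, min_seg=min_seg, penalty=penalty)
    candidates = extract_bouts(cp, v)
    truncated = [truncate_bout(b, v, truncation_run) for b in candidates]
    bouts = filter_bouts(truncated, ts.frame_rate, min_dur, t0=ts.start_offset)
    summary = classify_freezing(bouts, events) if events is not None else {}
    return FreezingResult(thr, v, cp, bouts, summary)
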