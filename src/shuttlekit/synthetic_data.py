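"""Synthetic two-way active-avoidance sessions with full ground truth.

The generator emulates the data streams the analysis consumes — pose
tracking, WS/US/OPTO event logs, and two-channel photometry — with the
statistical structure the detectors assume, so that every downstream stage
can be tested without recorded data.

Task contingency (honored exactly): each of the ``n_trials`` warning
signals lasts up to ``ws_max_dur`` s; a hurdle crossing during the WS
truncates it and prevents the footshock (avoidance), otherwise the US
comes on at WS end and stays on until the crossing (escape). The
inter-trial interval separates presentations.

Trajectory model: piecewise behavioral states {freeze, ambulate, shuttle}
with Gaussian jitter — freezing is near-zero coincident displacement of
nose and body center, ambulation a bounded random walk inside the current
chamber, and shuttles smooth accelerating runs that cross the hurdle at the
planned frame. Photometry: signal channel = baseline x bleach x
(1 + transients) + shared motion artifact + noise; isosbestic channel = an
affine map of (baseline x bleach + artifact) + noise, carrying no
transients. Transients use a difference-of-exponentials kernel normalized
to unit peak (a standard GCaMP proxy); the response map places an
outcome-dependent WS-onset response, a pre-shuttle dip, an optogenetic
suppression during the light and a rebound transient starting exactly at
light offset.

All times are seconds on the session master clock; the tracking and
photometry streams carry independent start offsets so stream alignment is
a real operation downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .session_io import EventLog, Geometry, PhotometryTrace, Session, TrackingSeries, align_streams

FREEZE_JITTER_MM = 0.007      # per-coordinate SD of positional jitter when frozen
AMBULATE_SPEED_MM = (3.0, 1.0)  # per-frame step length mean/SD, clipped below
AMBULATE_SPEED_CLIP = (0.5, 7.0)
HEAD_OFFSET_MM = 25.0         # nose leads the body center along the heading
SHUTTLE_RUN_S = 0.8           # initiate-to-crossing duration
SHUTTLE_SETTLE_S = 0.2        # deceleration after the crossing
WALL_MARGIN_MM = 15.0
HURDLE_MARGIN_MM = 25.0       # ambulation keeps clear of the hurdle band


class ConfigError(ValueError):
    def __init__(self, fld: str, message: str):
        super().__init__(f"invalid configuration field '{fld}': {message}")
        self.field = fld


class PlanError(ValueError):
    pass


@dataclass
class SessionConfig:
    """Task and generator constants; defaults mirror the training protocol
    (30 WS presentations of up to 15 s, 30 s ITI) at 30 Hz video."""

    n_trials: int = 30
    ws_max_dur: float = 15.0
    iti_dur: float = 30.0
    frame_rate: float = 30.0
    photometry_rate: float = 100.0
    box_length: float = 360.0
    box_width: float = 180.0
    hurdle_pos: float = 180.0
    avoid_prob: float = 0.8
    avoid_latency_dist: tuple[float, float] = (5.0, 1.5)
    escape_latency_dist: tuple[float, float] = (0.8, 0.2)
    freezing_rate: float = 6.0              # bouts / min
    freezing_dur_dist: tuple[float, float] = (3.0, 1.0)
    seed: int = 0
    lead_in_s: float = 5.0
    opto_light: bool = False                # light from WS-5s to WS offset+5s
    opto_margin_s: float = 5.0
    tracking_offset: float = 0.0
    photometry_offset: float = 0.37
    gap_rate_per_min: float = 1.0           # missing-position dropouts
    gap_max_frames: int = 6

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials", f"{self.n_trials} must be >= 1")
        for name in ("ws_max_dur", "iti_dur", "frame_rate", "photometry_rate",
                     "box_length", "box_width", "lead_in_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, f"{getattr(self, name)} must be > 0")
        if not 0.0 <= self.avoid_prob <= 1.0:
            raise ConfigError("avoid_prob", f"{self.avoid_prob} not in [0, 1]")
        if not 0.0 < self.hurdle_pos < self.box_length:
            raise ConfigError("hurdle_pos",
                              f"{self.hurdle_pos} not strictly inside (0, {self.box_length})")
        for name in ("avoid_latency_dist", "escape_latency_dist", "freezing_dur_dist"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ConfigError(name, f"({mean}, {sd}) needs mean > 0, sd >= 0")
        if self.freezing_rate < 0:
            raise ConfigError("freezing_rate", "must be >= 0")
        if self.gap_max_frames < 0 or self.gap_rate_per_min < 0:
            raise ConfigError("gap_rate_per_min", "gap parameters must be >= 0")


@dataclass
class PhotometryModel:
    """Emission model for the demodulated photometry channels (a.u.)."""

    baseline_f: float = 2.0
    bleach_tau: float = 300.0
    bleach_amp: float = 0.3
    motion_artifact_sd: float = 0.05
    transient_rise_tau: float = 0.2
    transient_decay_tau: float = 1.5
    ws_amp_avoidance: float = 0.05
    ws_amp_escape: float = 0.02
    preshuttle_dip_amp: float = 0.04
    preshuttle_lead_s: float = 1.0
    opto_suppression_depth: float = 0.5
    rebound_amp: float = 0.4
    noise_sd: float = 0.004
    iso_gain: float = 0.6
    iso_offset: float = 0.2

    def validate(self) -> None:
        if not self.transient_decay_tau > self.transient_rise_tau > 0:
            raise ConfigError("transient_decay_tau",
                              "kinetics require decay_tau > rise_tau > 0")
        if not 0 <= self.bleach_amp < 1:
            raise ConfigError("bleach_amp", f"{self.bleach_amp} not in [0, 1)")
        if self.opto_suppression_depth + self.preshuttle_dip_amp >= 1.0:
            raise ConfigError("opto_suppression_depth",
                              "suppression plus dip must leave fluorescence nonnegative")
        for name in ("baseline_f", "bleach_tau"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be > 0")
        for name in ("motion_artifact_sd", "noise_sd", "ws_amp_avoidance",
                     "ws_amp_escape", "preshuttle_dip_amp", "rebound_amp",
                     "opto_suppression_depth"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")


@dataclass
class TrialPlan:
    index: int
    outcome: str                 # avoidance | escape
    ws_onset: float
    ws_offset: float
    crossing: float
    initiate: float
    us_onset: Optional[float] = None
    us_offset: Optional[float] = None


@dataclass
class GroundTruth:
    freeze_bouts: list[tuple[float, float]]
    trial_outcomes: list[str]
    shuttle_times: list[float]
    shuttle_initiate_times: list[float]
    transient_times_amps: list[tuple[float, float, str]]
    tracking_offset: float = 0.0
    photometry_offset: float = 0.0


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def _snap(t: float, frame_rate: float) -> float:
    return round(t * frame_rate) / frame_rate


def plan_trials(cfg: SessionConfig, rng: np.random.Generator) -> tuple[list[TrialPlan], float]:
    """Draw outcomes and crossing times honoring the task contingency."""
    plans = []
    t = cfg.lead_in_s
    for i in range(cfg.n_trials):
        ws_onset = _snap(t, cfg.frame_rate)
        avoid = rng.random() < cfg.avoid_prob
        if avoid:
            m, s = cfg.avoid_latency_dist
            lat = float(np.clip(rng.normal(m, s), 1.5, cfg.ws_max_dur - 0.5))
            crossing = _snap(ws_onset + lat, cfg.frame_rate)
            plan = TrialPlan(i, "avoidance", ws_onset, crossing, crossing,
                             _snap(crossing - SHUTTLE_RUN_S, cfg.frame_rate))
            trial_end = crossing
        else:
            ws_offset = _snap(ws_onset + cfg.ws_max_dur, cfg.frame_rate)
            m, s = cfg.escape_latency_dist
            lat = float(np.clip(rng.normal(m, s), 0.3, 3.0))
            crossing = _snap(ws_offset + lat, cfg.frame_rate)
            plan = TrialPlan(i, "escape", ws_onset, ws_offset, crossing,
                             _snap(crossing - SHUTTLE_RUN_S, cfg.frame_rate),
                             us_onset=ws_offset, us_offset=crossing)
            trial_end = crossing
        plans.append(plan)
        t = trial_end + cfg.iti_dur
    total = t + 5.0  # tail after the last ITI
    return plans, _snap(total, cfg.frame_rate)


def plan_freezing(cfg: SessionConfig, plans: list[TrialPlan], total_s: float,
                  rng: np.random.Generator) -> list[tuple[float, float]]:
    """Freeze-bout plan avoiding shuttle-run windows; snapped to frames."""
    if cfg.freezing_rate <= 0:
        return []
    windows = [(p.initiate - 0.7, p.crossing + SHUTTLE_SETTLE_S + 0.5) for p in plans]
    mean_dur = cfg.freezing_dur_dist[0]
    mean_gap = max(60.0 / cfg.freezing_rate - mean_dur, 1.0)
    bouts: list[tuple[float, float]] = []
    t = 2.0
    while True:
        start = t + 1.5 + rng.exponential(mean_gap)
        dur = float(np.clip(rng.normal(*cfg.freezing_dur_dist), 1.2, 8.0))
        # slide past any shuttle window the bout would touch
        moved = True
        while moved:
            moved = False
            for w0, w1 in windows:
                if start < w1 and start + dur > w0:
                    start = w1 + 0.3
                    moved = True
        end = start + dur
        if end > total_s - 1.0:
            break
        bouts.append((_snap(start, cfg.frame_rate), _snap(end, cfg.frame_rate)))
        t = end
    return bouts


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _fold(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded walk into [lo, hi]."""
    period = 2.0 * (hi - lo)
    q = np.mod(p - lo, period)
    return lo + np.minimum(q, period - q)


def _chamber_bounds(cfg: SessionConfig, left: bool) -> tuple[float, float]:
    if left:
        return WALL_MARGIN_MM, cfg.hurdle_pos - HURDLE_MARGIN_MM
    return cfg.hurdle_pos + HURDLE_MARGIN_MM, cfg.box_length - WALL_MARGIN_MM


def generate_trajectory(cfg: SessionConfig, plans: list[TrialPlan],
                        freeze_plan: list[tuple[float, float]],
                        total_s: float, rng: np.random.Generator,
                        gap_plan: Optional[list[tuple[int, int]]] = None
                        ) -> TrackingSeries:
    """Synthesize nose and body-center tracks for the planned session.

    ``gap_plan`` is an optional list of (start_frame, n_frames) missing-
    position runs to insert. Raises :class:`PlanError` if a freeze bout
    overlaps a shuttle run.
    """
    fr = cfg.frame_rate
    n = int(round(total_s * fr)) + 1
    FREEZE, AMBULATE, RUN = 1, 0, 2
    state = np.zeros(n, dtype=int)
    run_spans: list[tuple[int, int, int]] = []  # (f0, f1 excl, crossing frame)
    for p in plans:
        f0 = int(round((p.initiate - cfg.tracking_offset) * fr))
        fc = int(round((p.crossing - cfg.tracking_offset) * fr))
        f1 = min(fc + int(round(SHUTTLE_SETTLE_S * fr)) + 1, n)
        state[f0:f1] = RUN
        run_spans.append((f0, f1, fc))
    for b0, b1 in freeze_plan:
        a = int(round((b0 - cfg.tracking_offset) * fr))
        b = int(round((b1 - cfg.tracking_offset) * fr))
        if (state[a:b] == RUN).any():
            raise PlanError(f"freeze bout ({b0:.2f}, {b1:.2f}) overlaps a shuttle run")
        state[a:b] = FREEZE

    center = np.zeros((n, 2))
    heading = np.zeros(n)
    left = True
    lo, hi = _chamber_bounds(cfg, left)
    pos = np.array([(lo + hi) / 2.0, cfg.box_width / 2.0])
    h = 0.0
    run_lookup = {f0: (f1, fc) for f0, f1, fc in run_spans}

    i = 0
    while i < n:
        s = state[i]
        j = i
        while j < n and state[j] == s:
            j += 1
        length = j - i
        if s == FREEZE:
            center[i:j] = pos + rng.normal(0.0, FREEZE_JITTER_MM, (length, 2))
            heading[i:j] = h
            # pos unchanged
        elif s == AMBULATE:
            dh = rng.normal(0.0, 0.4, length)
            hs = h + np.cumsum(dh)
            speed = np.clip(rng.normal(*AMBULATE_SPEED_MM, length),
                            *AMBULATE_SPEED_CLIP)
            steps = np.column_stack([speed * np.cos(hs), speed * np.sin(hs)])
            path = pos + np.cumsum(steps, axis=0)
            path[:, 0] = _fold(path[:, 0], lo, hi)
            path[:, 1] = _fold(path[:, 1], WALL_MARGIN_MM,
                               cfg.box_width - WALL_MARGIN_MM)
            center[i:j] = path
            heading[i:j] = hs
            pos = center[j - 1].copy()
            h = float(hs[-1])
        else:  # shuttle run
            _, fc = run_lookup.get(i, (j, min(i + int(SHUTTLE_RUN_S * fr), n - 1)))
            direction = 1.0 if left else -1.0
            x0 = pos[0]
            x_cross = cfg.hurdle_pos + direction * 6.0
            d = abs(x_cross - x0)
            k_cross = max(min(fc, j - 1) - i, 1)
            # accelerate over the final k_eff frames so the last step is large
            # enough (>= ~7 mm) that the first sample past the hurdle is the
            # planned crossing frame, even for starts close to the hurdle
            k_eff = int(min(k_cross, max(3, math.floor(d / 4.0))))
            hold = k_cross - k_eff
            q = np.arange(length, dtype=float)
            x = np.full(length, x0)
            if hold > 0:
                x[:hold] += rng.normal(0.0, 0.3, hold)
            approach = np.clip((q - hold) / k_eff, 0.0, 1.0)
            run_mask = q >= hold
            x[run_mask] = x0 + (x_cross - x0) * approach[run_mask] ** 2
            if length > k_cross + 1:
                x_stop = cfg.hurdle_pos + direction * 45.0
                m = length - k_cross - 1
                ease = 1.0 - (1.0 - (q[k_cross + 1:] - k_cross) / max(m, 1)) ** 2
                x[k_cross + 1:] = x_cross + (x_stop - x_cross) * ease
            y0 = pos[1]
            y = y0 + (cfg.box_width / 2.0 - y0) * q / max(length - 1, 1)
            center[i:j, 0] = x
            center[i:j, 1] = y
            heading[i:j] = 0.0 if direction > 0 else math.pi
            left = not left
            lo, hi = _chamber_bounds(cfg, left)
            pos = center[j - 1].copy()
            h = heading[j - 1]
        i = j

    nose_jitter = np.where(state == FREEZE, FREEZE_JITTER_MM, 0.25)[:, None]
    nose = center + HEAD_OFFSET_MM * np.column_stack([np.cos(heading), np.sin(heading)])
    nose += rng.normal(0.0, 1.0, (n, 2)) * nose_jitter

    if gap_plan:
        for start, length in gap_plan:
            if start < 0 or start + length > n:
                raise PlanError(f"gap ({start}, {length}) outside the series")
            nose[start:start + length] = np.nan
            center[start:start + length] = np.nan
    return TrackingSeries(fr, cfg.tracking_offset, nose, center)


def _draw_gap_plan(cfg: SessionConfig, plans: list[TrialPlan], n_frames: int,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random missing-position dropouts, kept clear of shuttle runs."""
    if cfg.gap_rate_per_min <= 0 or cfg.gap_max_frames <= 0:
        return []
    fr = cfg.frame_rate
    total_min = n_frames / fr / 60.0
    n_gaps = rng.poisson(cfg.gap_rate_per_min * total_min)
    protected = [(int((p.initiate - 0.3) * fr), int((p.crossing + 0.5) * fr))
                 for p in plans]
    out = []
    for _ in range(n_gaps):
        length = int(rng.integers(1, cfg.gap_max_frames + 1))
        start = int(rng.integers(20, max(n_frames - length - 20, 21)))
        if any(start < b and start + length > a for a, b in protected):
            continue
        out.append((start, length))
    return out


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials kernel, unit peak, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    out = np.where(t >= 0.0,
                   np.exp(-np.clip(t, 0, None) / decay_tau)
                   - np.exp(-np.clip(t, 0, None) / rise_tau), 0.0)
    return out / peak


def generate_photometry(cfg: SessionConfig, pm: PhotometryModel,
                        events: EventLog, plans: list[TrialPlan],
                        total_s: float, rng: np.random.Generator
                        ) -> tuple[PhotometryTrace, list[tuple[float, float, str]]]:
    """Two-channel trace plus the ground-truth transient placements."""
    if cfg.photometry_rate <= 0:
        raise ConfigError("photometry_rate", "must be > 0")
    rate = cfg.photometry_rate
    n = int(round((total_s - cfg.photometry_offset) * rate))
    t = cfg.photometry_offset + np.arange(n) / rate

    bleach = (1.0 - pm.bleach_amp) + pm.bleach_amp * np.exp(-t / pm.bleach_tau)
    base = pm.baseline_f * bleach

    transients = np.zeros(n)
    placed: list[tuple[float, float, str]] = []

    def add_kernel(t0: float, amp: float, kind: str) -> None:
        if amp == 0.0:
            return
        i0 = max(int(math.ceil((t0 - t[0]) * rate)), 0)
        i1 = min(i0 + int(10.0 * pm.transient_decay_tau * rate), n)
        if i0 >= n:
            return
        transients[i0:i1] += amp * transient_kernel(
            t[i0:i1] - t0, pm.transient_rise_tau, pm.transient_decay_tau)
        placed.append((t0, amp, kind))

    for p in plans:
        ws_amp = pm.ws_amp_avoidance if p.outcome == "avoidance" else pm.ws_amp_escape
        add_kernel(p.ws_onset, ws_amp, "ws_onset")
        add_kernel(p.initiate - pm.preshuttle_lead_s, -pm.preshuttle_dip_amp,
                   "pre_shuttle_dip")
    for _, row in events.of_kind("OPTO").iterrows():
        on, off = float(row["onset_s"]), float(row["offset_s"])
        mask = (t >= on) & (t < off)
        transients[mask] -= pm.opto_suppression_depth
        if pm.opto_suppression_depth:
            placed.append((on, -pm.opto_suppression_depth, "opto_suppression"))
        add_kernel(off, pm.rebound_amp, "rebound")

    artifact = np.zeros(n)
    if pm.motion_artifact_sd > 0:
        raw = gaussian_filter1d(rng.standard_normal(n), sigma=0.3 * rate)
        artifact = raw / max(raw.std(), 1e-12) * pm.motion_artifact_sd

    f_signal = base * (1.0 + transients) + artifact \
        + rng.normal(0.0, pm.noise_sd, n)
    f_iso = pm.iso_gain * (base + artifact) + pm.iso_offset \
        + rng.normal(0.0, pm.noise_sd, n)
    return PhotometryTrace(rate, cfg.photometry_offset, f_signal, f_iso), placed


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def build_event_log(cfg: SessionConfig, plans: list[TrialPlan]) -> EventLog:
    rows = []
    for p in plans:
        rows.append(("WS", p.ws_onset, p.ws_offset, p.index))
        if p.outcome == "escape":
            rows.append(("US", p.us_onset, p.us_offset, p.index))
        if cfg.opto_light:
            rows.append(("OPTO", p.ws_onset - cfg.opto_margin_s,
                         p.ws_offset + cfg.opto_margin_s, p.index))
        trial_end = (p.us_offset if p.outcome == "escape" else p.ws_offset) + cfg.iti_dur
        rows.append(("TRIAL", p.ws_onset, trial_end, p.index))
    table = pd.DataFrame(rows, columns=["kind", "onset_s", "offset_s", "trial"])
    return EventLog(table)


def generate_session(cfg: SessionConfig, pm: PhotometryModel | None = None,
                     include_photometry: bool = True
                     ) -> tuple[Session, GroundTruth]:
    """Generate an aligned session and its ground truth; fully seeded.

    Identical (cfg, pm) — the seed lives in ``cfg.seed`` — produce
    bit-identical output.
    """
    cfg.validate()
    pm = pm or PhotometryModel()
    pm.validate()
    rng = np.random.default_rng(cfg.seed)

    plans, total_s = plan_trials(cfg, rng)
    freeze_plan = plan_freezing(cfg, plans, total_s, rng)
    events = build_event_log(cfg, plans)
    n_frames = int(round(total_s * cfg.frame_rate)) + 1
    gap_plan = _draw_gap_plan(cfg, plans, n_frames, rng)
    tracking = generate_trajectory(cfg, plans, freeze_plan, total_s, rng,
                                   gap_plan=gap_plan)
    photometry, placed = (None, [])
    if include_photometry:
        photometry, placed = generate_photometry(cfg, pm, events, plans,
                                                 total_s, rng)

    geometry = Geometry(cfg.box_length, cfg.box_width, cfg.hurdle_pos)
    session = align_streams(tracking, events, photometry, geometry)

    starts = [cfg.tracking_offset, float(events.table["onset_s"].min())]
    if photometry is not None:
        starts.append(cfg.photometry_offset)
    t0 = min(starts)
    gt = GroundTruth(
        freeze_bouts=[(a - t0, b - t0) for a, b in freeze_plan],
        trial_outcomes=[p.outcome for p in plans],
        shuttle_times=[p.crossing - t0 for p in plans],
        shuttle_initiate_times=[p.initiate - t0 for p in plans],
        transient_times_amps=[(tt - t0, a, k) for tt, a, k in placed],
        tracking_offset=cfg.tracking_offset - t0,
        photometry_offset=(cfg.photometry_offset - t0) if photometry is not None else 0.0,
    )
    return session, gt


def generate_psc_trace(amp1: float, amp2: float, isi_ms: float = 50.0,
                       kinetics: tuple[float, float] = (1.0, 8.0),
                       rate: float = 20000.0, duration_s: float = 0.4,
                       polarity: str = "negative", noise_pa: float = 0.0,
                       seed: int = 0) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Two PSC-shaped deflections with known peak amplitudes (pA).

    ``kinetics`` are (rise_ms, decay_ms) of the difference-of-exponentials
    kernel. Returns (trace, rate, (stim1_s, stim2_s)).
    """
    if isi_ms <= 0:
        raise ConfigError("isi_ms", "inter-stimulus interval must be > 0")
    rise, decay = kinetics
    if not decay > rise > 0:
        raise ConfigError("kinetics", "need decay_ms > rise_ms > 0")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    stim1 = 0.1
    stim2 = stim1 + isi_ms * 1e-3
    sign = -1.0 if polarity == "negative" else 1.0
    trace = sign * (amp1 * transient_kernel(t - stim1, rise * 1e-3, decay * 1e-3)
                    + amp2 * transient_kernel(t - stim2, rise * 1e-3, decay * 1e-3))
    if noise_pa > 0:
        trace = trace + np.random.default_rng(seed).normal(0.0, noise_pa, n)
    return trace, rate, (stim1, stim2)


def config_from_dict(doc: dict) -> tuple[SessionConfig, PhotometryModel]:
    """Build (SessionConfig, PhotometryModel) from a JSON/YAML-style mapping
    with optional 'session' and 'photometry' sub-documents."""
    session_doc = dict(doc.get("session", {}))
    pm_doc = dict(doc.get("photometry", {}))
    for key in ("avoid_latency_dist", "escape_latency_dist", "freezing_dur_dist"):
        if key in session_doc:
            session_doc[key] = tuple(session_doc[key])
    try:
        cfg = SessionConfig(**session_doc)
        pm = PhotometryModel(**pm_doc)
    except TypeError as exc:
        raise ConfigError("<document>", str(exc)) from exc
    cfg.validate()
    pm.validate()
    return cfg, pm
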