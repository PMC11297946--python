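"""Isosbestic correction, dF/F, z-scoring, PETHs and AUC quantification.

The calcium-dependent channel (473 nm excitation) and the
calcium-independent isosbestic channel (405 nm) share bleaching and motion
artifacts but only the former carries activity transients. The correction
is an ordinary least-squares fit of the signal channel on the isosbestic
channel over the whole session, producing a fitted control F_fit; then

    dF/F = (F_signal - F_fit) / F_fit.

Event-locked analysis builds peri-event matrices (PETHs) of z-scored dF/F,
with the pre-event portion of each extracted window serving as that trial's
z baseline; the wide warning-signal heatmap window is (-10, +30) s and the
peri-event windows are +/-2 s for WS onset and +/-5 s for the other
behavioral events. Quantification integrates the z-score in contiguous
1-s bins (trapezoidal rule) and over named epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .session_io import PhotometryTrace

logger = logging.getLogger(__name__)

# peri-event windows (pre_s, post_s), symmetric about the event
WINDOWS = {
    "ws_onset": (2.0, 2.0),
    "max_velocity": (5.0, 5.0),
    "shuttle_initiate": (5.0, 5.0),
    "shuttle": (5.0, 5.0),
    "ws_freezing": (5.0, 5.0),
}
HEATMAP_WINDOW = (10.0, 30.0)  # wide WS-onset window for session heatmaps


class DegenerateFitError(ValueError):
    pass


@dataclass
class DFFTrace:
    t: np.ndarray
    dff: np.ndarray
    fit: tuple[float, float]  # (slope, intercept) of signal ~ isosbestic
    n_masked: int = 0

    def __len__(self) -> int:
        return self.dff.size


@dataclass
class PETH:
    event: str
    window: tuple[float, float]  # (pre_s, post_s), both positive
    matrix: np.ndarray           # trials x samples, z-scored
    rate: float
    labels: list[dict] = field(default_factory=list)  # outcome/latency per row
    baseline: str = "pre_event"

    @property
    def time(self) -> np.ndarray:
        """Sample times relative to the event; window edges at -pre and +post."""
        pre, post = self.window
        n = int(round((pre + post) * self.rate))
        return -pre + np.arange(n) / self.rate

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0) if self.n_trials else np.empty(0)


@dataclass
class BinnedAUC:
    event: str
    edges: np.ndarray   # bin edges (s) relative to the event, contiguous, 1 s wide
    values: np.ndarray  # trials x bins, z*s
    labels: list[dict] = field(default_factory=list)


def fit_isosbestic(trace: PhotometryTrace) -> tuple[float, float]:
    """OLS fit of the signal channel on the isosbestic channel (whole session)."""
    if len(trace) < 2:
        raise ValueError("need at least 2 samples for the isosbestic fit")
    x, y = trace.f_iso, trace.f_signal
    if np.ptp(x) == 0:
        raise DegenerateFitError("isosbestic channel is constant; fit is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def compute_dff(trace: PhotometryTrace, fit: tuple[float, float] | None = None) -> DFFTrace:
    """dF/F = (F_signal - F_fit) / F_fit with F_fit = slope*F_iso + intercept.

    Samples with non-positive fitted control are masked NaN and counted.
    """
    if fit is None:
        fit = fit_isosbestic(trace)
    slope, intercept = fit
    f_fit = slope * trace.f_iso + intercept
    bad = f_fit <= 0
    n_masked = int(bad.sum())
    if n_masked:
        logger.warning("%d sample(s) with non-positive fitted control masked", n_masked)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (trace.f_signal - f_fit) / f_fit
    dff[bad] = np.nan
    return DFFTrace(trace.times, dff, (slope, intercept), n_masked)


def zscore(dff: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """(dff - mean(baseline)) / sd(baseline); errors on zero baseline SD."""
    baseline = np.asarray(baseline, float)
    baseline = baseline[np.isfinite(baseline)]
    if baseline.size == 0:
        raise ValueError("empty baseline window")
    sd = baseline.std()
    if sd == 0:
        raise ValueError("baseline SD is zero; z-score undefined")
    return (np.asarray(dff, float) - baseline.mean()) / sd


def build_peth(dff: DFFTrace, event_times: np.ndarray, event: str = "ws_onset",
               window: tuple[float, float] | None = None,
               labels: list[dict] | None = None,
               min_baseline_s: float = 1.0) -> PETH:
    """Extract per-trial z-scored windows around event times.

    Each row is z-scored against its own pre-event samples. Events whose
    window falls outside the trace (or whose baseline SD is degenerate) are
    dropped with a warning.
    """
    if window is None:
        window = WINDOWS.get(event, (5.0, 5.0))
    pre, post = window
    rate = 1.0 / float(np.median(np.diff(dff.t))) if len(dff) > 1 else 1.0
    n = int(round((pre + post) * rate))
    n_pre = int(round(pre * rate))
    if n_pre / rate < min_baseline_s:
        logger.warning("pre-event window %.2fs is shorter than %.1fs of baseline",
                       pre, min_baseline_s)
    rows, kept = [], []
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    t0 = dff.t[0] if len(dff) else 0.0
    for j, ev in enumerate(event_times):
        i0 = int(round((ev - pre - t0) * rate))
        if i0 < 0 or i0 + n > len(dff):
            logger.warning("event at %.2fs too close to the trace edge; row dropped", ev)
            continue
        seg = dff.dff[i0:i0 + n]
        base = seg[:n_pre]
        if not np.isfinite(seg).all():
            logger.warning("event at %.2fs overlaps masked samples; row dropped", ev)
            continue
        try:
            rows.append(zscore(seg, base))
        except ValueError:
            logger.warning("event at %.2fs has degenerate baseline; row dropped", ev)
            continue
        kept.append(j)
    matrix = np.vstack(rows) if rows else np.empty((0, n))
    row_labels = [labels[j] for j in kept] if labels else [{} for _ in kept]
    return PETH(event, window, matrix, rate, row_labels)


def binned_auc(peth: PETH) -> BinnedAUC:
    """Trapezoidal AUC of the z-score in contiguous 1-s bins over the window.

    A non-integer window length drops the final partial bin with a warning.
    Adjacent bins share their edge sample, so the bin AUCs add up to the
    whole-window trapezoid.
    """
    pre, post = peth.window
    total = pre + post
    n_bins = int(np.floor(total + 1e-9))
    if abs(total - n_bins) > 1e-9:
        logger.warning("window length %.2fs is not an integer number of seconds; "
                       "final partial bin dropped", total)
    r = int(round(peth.rate))
    dt = 1.0 / peth.rate
    n_samp = peth.matrix.shape[1]
    values = np.zeros((peth.n_trials, n_bins))
    for b in range(n_bins):
        s0, s1 = b * r, min((b + 1) * r, n_samp - 1)
        values[:, b] = np.trapezoid(peth.matrix[:, s0:s1 + 1], dx=dt, axis=1)
    edges = -pre + np.arange(n_bins + 1, dtype=float)
    return BinnedAUC(peth.event, edges, values, peth.labels)


def epoch_auc(z: np.ndarray, t: np.ndarray, epochs: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Trapezoidal AUC of a z-scored series over named, non-overlapping epochs."""
    spans = sorted(epochs.items(), key=lambda kv: kv[1][0])
    for (name_a, (a0, a1)), (name_b, (b0, b1)) in zip(spans[:-1], spans[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError(f"epochs '{name_a}' and '{name_b}' overlap")
    out = {}
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    for name, (e0, e1) in epochs.items():
        if e1 <= e0:
            raise ValueError(f"epoch '{name}' has non-positive duration")
        mask = (t >= e0 - 1e-9) & (t <= e1 + 1e-9)
        if mask.sum() < 2:
            raise ValueError(f"epoch '{name}' ({e0}, {e1}) lies outside the trace")
        out[name] = float(np.trapezoid(z[mask], t[mask]))
    return out


def order_heatmap(peth: PETH) -> np.ndarray:
    """Row order for heatmap display.

    Avoidance rows: ascending latency (missing latency sorts last, with a
    warning). Escape rows: ascending change from baseline during the WS
    (mean z after the event minus mean z before it) — reduced to increased.
    Mixed PETHs order avoidance rows first.
    """
    n_pre = int(round(peth.window[0] * peth.rate))
    keys = []
    for i, lab in enumerate(peth.labels):
        outcome = lab.get("outcome", "avoidance")
        if outcome == "avoidance":
            lat = lab.get("latency")
            if lat is None:
                logger.warning("avoidance row %d has no latency; placed last", i)
                lat = np.inf
            keys.append((0, float(lat), i))
        else:
            row = peth.matrix[i]
            delta = row[n_pre:].mean() - row[:n_pre].mean()
            keys.append((1, float(delta), i))
    return np.array([i for _, _, i in sorted(keys)], dtype=int)
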