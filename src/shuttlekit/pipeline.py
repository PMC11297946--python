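"""End-to-end session analysis: freezing, trials, photometry, statistics.

``analyze_session`` consumes an aligned :class:`~shuttlekit.session_io.Session`
and produces all tabular outputs; ``run_analysis`` wraps it with bundle
reading, gap interpolation and alignment, and writes the report directory:

* ``freezing.csv``           — one row per freezing bout
* ``trials.csv``             — one row per trial with all endpoints
* ``behavior_summary.json``  — session-level behavioral summary
* ``peth_<event>.csv``       — trials x time z-score matrices with labels
* ``auc_bins_<event>.csv``   — 1-s-bin AUCs per trial
* ``epoch_auc.csv``          — pre/during/post epoch AUCs per trial
* ``stats_<event>.csv``      — per-bin comparisons (BKY-corrected)
* ``stats_summary.json``     — first-significant-change bins per trial type
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import freezing as fz
from . import photometry as ph
from . import stats as st
from . import trials as tr
from .session_io import Session, interpolate_gaps, read_session, align_streams

logger = logging.getLogger(__name__)

PETH_EVENTS = ("ws_onset", "max_velocity", "shuttle_initiate", "shuttle", "ws_freezing")


def _event_times(event: str, trial_list: list[tr.Trial],
                 bouts: list[fz.FreezeBout]) -> tuple[list[float], list[dict]]:
    """Per-trial event times plus row labels for PETH construction."""
    times, labels = [], []
    if event == "ws_freezing":
        for b in bouts:
            if b.context == "WS":
                times.append(b.start_s)
                labels.append({"outcome": "freezing", "latency": None})
        return times, labels
    attr = {"ws_onset": "ws_onset_s", "max_velocity": "max_velocity_s",
            "shuttle_initiate": "shuttle_initiate_s", "shuttle": "shuttle_s"}[event]
    for t in trial_list:
        value = getattr(t, attr)
        if value is None or t.outcome == "invalid":
            continue
        times.append(value)
        labels.append({"outcome": t.outcome,
                       "latency": t.latency_avoid_s if t.outcome == "avoidance"
                       else t.latency_escape_s,
                       "trial": t.index})
    return times, labels


def _epoch_rows(dff: ph.DFFTrace, session: Session,
                trial_list: list[tr.Trial]) -> pd.DataFrame:
    """Per-trial pre/during/post epoch AUCs.

    With an optogenetic light the epochs bracket the light window
    (pre-opto / opto / post-opto); otherwise they bracket the WS
    (pre-WS baseline / WS / post-WS). The z baseline is the pre epoch.
    """
    opto = session.events.of_kind("OPTO")
    rows = []
    for k, t in enumerate(trial_list):
        if opto is not None and len(opto) > k:
            on, off = float(opto.iloc[k]["onset_s"]), float(opto.iloc[k]["offset_s"])
            epochs = {"pre": (on - 5.0, on), "during": (on, off),
                      "post": (off, off + 5.0)}
        else:
            on, off = t.ws_onset_s, t.ws_offset_s
            epochs = {"pre": (on - 5.0, on), "during": (on, off),
                      "post": (off, off + 5.0)}
        lo, hi = epochs["pre"][0], epochs["post"][1]
        mask = (dff.t >= lo - 1e-9) & (dff.t <= hi + 1e-9)
        if mask.sum() < 2:
            logger.warning("trial %d epochs outside the photometry trace; skipped",
                           t.index)
            continue
        base_mask = (dff.t >= epochs["pre"][0]) & (dff.t < epochs["pre"][1])
        if not np.isfinite(dff.dff[mask]).all() or base_mask.sum() < 2:
            continue
        try:
            z = ph.zscore(dff.dff, dff.dff[base_mask])
        except ValueError:
            continue
        try:
            aucs = ph.epoch_auc(z, dff.t, epochs)
        except ValueError:
            continue
        rows.append({"trial": t.index, "outcome": t.outcome, **aucs})
    return pd.DataFrame(rows)


def analyze_session(session: Session, alpha: float = 0.05) -> dict:
    """Run every analysis stage on an aligned session; returns a results dict."""
    results: dict = {}

    freeze = fz.detect_freezing(session.tracking, session.events)
    results["freezing"] = freeze

    crossings, _ = tr.detect_shuttles(session)
    ws = session.events.of_kind("WS")
    ws_max = float((ws["offset_s"] - ws["onset_s"]).max()) if len(ws) else 15.0
    trial_list = tr.classify_trials(session.events, crossings, ws_max=ws_max)
    tr.annotate_trials(session, trial_list, freeze.threshold)
    results["trials"] = trial_list
    results["behavior"] = tr.session_behavior(trial_list, freeze.summary)

    if session.photometry is not None:
        dff = ph.compute_dff(session.photometry)
        results["dff"] = dff
        peths, aucs, stats_tables, first_changes = {}, {}, {}, {}
        for event in PETH_EVENTS:
            times, labels = _event_times(event, trial_list, freeze.bouts)
            peth = ph.build_peth(dff, np.asarray(times), event=event, labels=labels)
            peths[event] = peth
            if peth.n_trials == 0:
                continue
            auc = ph.binned_auc(peth)
            aucs[event] = auc
            rows_a = np.array([lab.get("outcome") == "avoidance" for lab in auc.labels])
            comparisons: list[st.BinComparison] = []
            if 2 <= rows_a.sum() and 2 <= (~rows_a).sum():
                comparisons = st.compare_bins_between(
                    auc.values[rows_a], auc.values[~rows_a], auc.edges,
                    comparison="avoidance_vs_escape", alpha=alpha)
            for name, rows in (("avoidance", rows_a), ("escape", ~rows_a)):
                if rows.sum() >= 2:
                    first, within = st.first_significant_change(
                        auc.values[rows], auc.edges,
                        comparison=f"{name}_bin_vs_previous", alpha=alpha)
                    first_changes[f"{event}:{name}"] = first
                    comparisons.extend(within)
            stats_tables[event] = comparisons
        # wide warning-signal heatmap
        times, labels = _event_times("ws_onset", trial_list, freeze.bouts)
        heat = ph.build_peth(dff, np.asarray(times), event="ws_heatmap",
                             window=ph.HEATMAP_WINDOW, labels=labels)
        results["peths"] = peths
        results["heatmap"] = heat
        results["heatmap_order"] = ph.order_heatmap(heat)
        results["aucs"] = aucs
        results["stats"] = stats_tables
        results["first_changes"] = first_changes
        results["epoch_auc"] = _epoch_rows(dff, session, trial_list)
    return results


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_report(results: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    freeze: fz.FreezingResult = results["freezing"]
    pd.DataFrame([{"start_s": b.start_s, "end_s": b.end_s,
                   "duration_s": b.duration_s, "context": b.context,
                   "truncated": b.truncated} for b in freeze.bouts]
                 ).to_csv(out / "freezing.csv", index=False)

    pd.DataFrame([dataclasses.asdict(t) for t in results["trials"]]
                 ).to_csv(out / "trials.csv", index=False)
    with open(out / "behavior_summary.json", "w") as fh:
        json.dump({k: _jsonable(v) for k, v in results["behavior"].items()},
                  fh, indent=1, sort_keys=True)

    if "peths" in results:
        for event, peth in results["peths"].items():
            _write_peth(peth, out / f"peth_{event}.csv")
        _write_peth(results["heatmap"], out / "peth_ws_heatmap.csv",
                    order=results["heatmap_order"])
        for event, auc in results["aucs"].items():
            df = pd.DataFrame(auc.values,
                              columns=[f"bin_{e0:+.0f}s" for e0 in auc.edges[:-1]])
            df.insert(0, "outcome", [lab.get("outcome") for lab in auc.labels])
            df.to_csv(out / f"auc_bins_{event}.csv", index=False)
        for event, comparisons in results["stats"].items():
            pd.DataFrame([dataclasses.asdict(c) for c in comparisons]
                         ).to_csv(out / f"stats_{event}.csv", index=False)
        results["epoch_auc"].to_csv(out / "epoch_auc.csv", index=False)
        with open(out / "stats_summary.json", "w") as fh:
            json.dump({k: _jsonable(v) for k, v in results["first_changes"].items()},
                      fh, indent=1, sort_keys=True)
    return out


def _write_peth(peth: ph.PETH, path: Path, order: Optional[np.ndarray] = None) -> None:
    idx = order if order is not None else np.arange(peth.n_trials)
    df = pd.DataFrame(peth.matrix[idx] if peth.n_trials else peth.matrix,
                      columns=[f"t{t:+.3f}" for t in peth.time])
    df.insert(0, "outcome", [peth.labels[i].get("outcome") for i in idx])
    df.insert(1, "latency", [peth.labels[i].get("latency") for i in idx])
    df.to_csv(path, index=False)


def run_analysis(session_dir, out_dir, max_gap: int = 10,
                 alpha: float = 0.05) -> dict:
    """Read a session bundle, interpolate gaps, align, analyze and report."""
    raw = read_session(session_dir)
    tracking = interpolate_gaps(raw.tracking, max_gap=max_gap)
    session = align_streams(tracking, raw.events, raw.photometry, raw.geometry)
    results = analyze_session(session, alpha=alpha)
    write_report(results, out_dir)
    return results
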