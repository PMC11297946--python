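"""Reading, validation, interpolation and time-alignment of session data streams.

A shuttle-box session is composed of three independently clocked streams:

* pose tracking of the animal's nose and body center (fixed frame rate),
* a typed event log (warning signal WS, footshock US, optogenetic light
  OPTO, and TRIAL bookkeeping intervals),
* an optional two-channel demodulated photometry trace (calcium-dependent
  signal channel plus calcium-independent isosbestic control channel).

On-disk layout of a session bundle (directory):

* ``tracking.csv`` — columns ``frame, nose_x, nose_y, center_x, center_y``;
  empty cells mark missing positions (never silently zero).
* ``events.csv``   — columns ``kind, onset_s, offset_s, trial``.
* ``photometry.csv`` — columns ``t_s, f_signal, f_iso``.
* ``meta.json``    — frame rate, sampling rate, clock offsets, geometry.

All positions are millimetres, all times seconds, frame indices 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_KINDS = ("WS", "US", "OPTO", "TRIAL")
BODY_PARTS = ("nose", "center")


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant."""


class AlignmentError(ValueError):
    """Streams cannot be expressed on a common clock."""


@dataclass
class Geometry:
    """Shuttle-box geometry in mm: two chambers separated by a hurdle."""

    box_length: float = 360.0
    box_width: float = 180.0
    hurdle_pos: float = 180.0

    def __post_init__(self) -> None:
        if not (0.0 < self.hurdle_pos < self.box_length):
            raise ValidationError(
                f"hurdle_pos={self.hurdle_pos} must lie strictly inside the box "
                f"(0, {self.box_length})"
            )


@dataclass
class TrackingSeries:
    """Time-stamped x-y positions of named body parts at a fixed frame rate.

    ``nose`` and ``center`` are float arrays of shape (n_frames, 2); missing
    positions are NaN in both coordinates.
    """

    frame_rate: float
    start_offset: float
    nose: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.nose = np.asarray(self.nose, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.frame_rate <= 0:
            raise ValidationError(f"frame_rate={self.frame_rate} must be > 0")
        if self.nose.shape != self.center.shape or self.nose.ndim != 2 or self.nose.shape[1] != 2:
            raise ValidationError(
                f"nose {self.nose.shape} and center {self.center.shape} must both be (n, 2)"
            )

    def __len__(self) -> int:
        return self.nose.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps on the stream's own clock plus its offset."""
        return self.start_offset + np.arange(len(self)) / self.frame_rate

    def copy(self) -> "TrackingSeries":
        return TrackingSeries(self.frame_rate, self.start_offset,
                              self.nose.copy(), self.center.copy())


@dataclass
class EventLog:
    """Typed intervals on the session clock, one row per interval."""

    table: pd.DataFrame  # columns: kind, onset_s, offset_s, trial

    REQUIRED = ("kind", "onset_s", "offset_s", "trial")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"event log missing required column(s): {missing}")
        t = self.table
        bad = t.index[t["offset_s"] < t["onset_s"]]
        if len(bad):
            raise ValidationError(f"event row(s) {list(bad)} have offset_s < onset_s")
        unknown = set(t["kind"]) - set(EVENT_KINDS)
        if unknown:
            raise ValidationError(f"unknown event kind(s): {sorted(unknown)}")
        ws = t[t["kind"] == "WS"].sort_values("onset_s")
        if len(ws) > 1 and (ws["onset_s"].to_numpy()[1:] < ws["offset_s"].to_numpy()[:-1]).any():
            raise ValidationError("WS intervals overlap")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind].sort_values("onset_s").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "EventLog":
        return EventLog(self.table.copy())


@dataclass
class PhotometryTrace:
    """Paired signal/isosbestic sample vectors with sampling rate and offset."""

    rate: float
    start_offset: float
    f_signal: np.ndarray
    f_iso: np.ndarray

    def __post_init__(self) -> None:
        self.f_signal = np.asarray(self.f_signal, dtype=float)
        self.f_iso = np.asarray(self.f_iso, dtype=float)
        if self.rate <= 0:
            raise ValidationError(f"photometry rate={self.rate} must be > 0")
        if self.f_signal.shape != self.f_iso.shape or self.f_signal.ndim != 1:
            raise ValidationError("signal and isosbestic channels must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return self.f_signal.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(len(self)) / self.rate

    def copy(self) -> "PhotometryTrace":
        return PhotometryTrace(self.rate, self.start_offset,
                               self.f_signal.copy(), self.f_iso.copy())


@dataclass
class Session:
    """Aligned bundle of tracking + events (+ optional photometry) + geometry."""

    tracking: TrackingSeries
    events: EventLog
    photometry: Optional[PhotometryTrace] = None
    geometry: Geometry = field(default_factory=Geometry)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_tracking(path, frame_rate: float = 30.0, start_offset: float = 0.0) -> TrackingSeries:
    """Read a tracking CSV (frame, nose_x, nose_y, center_x, center_y).

    Empty cells mark missing positions; a frame with any missing coordinate
    of a body part is treated as missing for that part.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["frame", "nose_x", "nose_y", "center_x", "center_y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    frames = df["frame"].to_numpy()
    if len(frames) > 1 and not (np.diff(frames) > 0).all():
        bad = int(np.argmax(np.diff(frames) <= 0)) + 2  # +2: header + 1-based
        raise ValidationError(f"{path}: non-monotone frame index at line {bad}")
    nose = df[["nose_x", "nose_y"]].to_numpy(dtype=float)
    center = df[["center_x", "center_y"]].to_numpy(dtype=float)
    # any-NaN coordinate invalidates the whole sample for that body part
    nose[np.isnan(nose).any(axis=1)] = np.nan
    center[np.isnan(center).any(axis=1)] = np.nan
    return TrackingSeries(frame_rate, start_offset, nose, center)


def read_events(path) -> EventLog:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EventLog.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    bad = df.index[df["offset_s"] < df["onset_s"]]
    if len(bad):
        # +2 converts 0-based data row to 1-based file line past the header
        lines = [int(i) + 2 for i in bad]
        raise ValidationError(f"{path}: offset_s < onset_s at line(s) {lines}")
    return EventLog(df)


def read_photometry(path, rate: float = 100.0, start_offset: Optional[float] = None) -> PhotometryTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["t_s", "f_signal", "f_iso"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if not (dt > 0).all():
            bad = int(np.argmax(dt <= 0)) + 2
            raise ValidationError(f"{path}: non-monotone timestamps at line {bad}")
        rate = 1.0 / float(np.median(dt))
    if start_offset is None:
        start_offset = float(t[0]) if len(t) else 0.0
    return PhotometryTrace(rate, start_offset,
                           df["f_signal"].to_numpy(dtype=float),
                           df["f_iso"].to_numpy(dtype=float))


def write_session(session: Session, out_dir) -> Path:
    """Serialize a Session bundle as {tracking,events,photometry}.csv + meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts = session.tracking
    trk = pd.DataFrame({
        "frame": np.arange(len(ts)),
        "nose_x": ts.nose[:, 0], "nose_y": ts.nose[:, 1],
        "center_x": ts.center[:, 0], "center_y": ts.center[:, 1],
    })
    trk.to_csv(out / "tracking.csv", index=False)
    session.events.table.to_csv(out / "events.csv", index=False)
    meta = {
        "frame_rate": ts.frame_rate,
        "tracking_offset": ts.start_offset,
        "geometry": dataclasses.asdict(session.geometry),
    }
    if session.photometry is not None:
        ph = session.photometry
        pd.DataFrame({"t_s": ph.times, "f_signal": ph.f_signal, "f_iso": ph.f_iso}
                     ).to_csv(out / "photometry.csv", index=False)
        meta["photometry_rate"] = ph.rate
        meta["photometry_offset"] = ph.start_offset
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return out


def read_session(session_dir) -> Session:
    """Read a Session bundle written by :func:`write_session` (not yet aligned)."""
    d = Path(session_dir)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    tracking = read_tracking(d / "tracking.csv",
                             frame_rate=meta["frame_rate"],
                             start_offset=meta.get("tracking_offset", 0.0))
    events = read_events(d / "events.csv")
    photometry = None
    ph_path = d / "photometry.csv"
    if ph_path.exists():
        photometry = read_photometry(ph_path,
                                     rate=meta.get("photometry_rate", 100.0),
                                     start_offset=meta.get("photometry_offset"))
    geometry = Geometry(**meta.get("geometry", {}))
    return Session(tracking, events, photometry, geometry)


# ---------------------------------------------------------------------------
# gap interpolation
# ---------------------------------------------------------------------------

def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], missing, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def interpolate_gaps(ts: TrackingSeries, max_gap: int = 10) -> TrackingSeries:
    """Linearly interpolate runs of missing positions of length <= ``max_gap``.

    Interpolation is per coordinate, linear in frame index, between the
    flanking observed frames. Longer runs — and runs touching either series
    boundary, which cannot be bracketed — are left missing and reported via
    the logger. Idempotent.
    """
    out = ts.copy()
    for arr in (out.nose, out.center):
        missing = np.isnan(arr[:, 0])
        for start, stop in _missing_runs(missing):
            length = stop - start
            if start == 0 or stop == len(arr):
                logger.warning("missing run [%d, %d) touches the series boundary; "
                               "left un-interpolated", start, stop)
                continue
            if length > max_gap:
                logger.warning("missing run [%d, %d) of %d frames exceeds max_gap=%d; "
                               "left un-interpolated", start, stop, length, max_gap)
                continue
            lo, hi = start - 1, stop  # flanking observed frames
            frac = (np.arange(start, stop) - lo) / (hi - lo)
            for c in (0, 1):
                arr[start:stop, c] = arr[lo, c] + frac * (arr[hi, c] - arr[lo, c])
    return out


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_streams(tracking: TrackingSeries, events: EventLog,
                  photometry: Optional[PhotometryTrace] = None,
                  geometry: Optional[Geometry] = None) -> Session:
    """Re-express all streams on a common clock with session start = 0.

    The session origin is the earliest instant covered by any stream (stream
    start offsets and the first event onset); every timestamp is shifted by
    that origin so relative intervals are preserved exactly. Streams with no
    temporal overlap raise :class:`AlignmentError`.
    """
    starts = [tracking.start_offset]
    ends = [tracking.start_offset + len(tracking) / tracking.frame_rate]
    if len(events):
        starts.append(float(events.table["onset_s"].min()))
        ends.append(float(events.table["offset_s"].max()))
    if photometry is not None:
        starts.append(photometry.start_offset)
        ends.append(photometry.start_offset + len(photometry) / photometry.rate)
    if max(starts) >= min(ends):
        raise AlignmentError(
            f"streams share no temporal overlap: latest start {max(starts):.3f}s "
            f">= earliest end {min(ends):.3f}s")
    t0 = min(starts)

    trk = tracking.copy()
    trk.start_offset -= t0
    ev_table = events.table.copy()
    ev_table["onset_s"] = ev_table["onset_s"] - t0
    ev_table["offset_s"] = ev_table["offset_s"] - t0
    pho = None
    if photometry is not None:
        pho = photometry.copy()
        pho.start_offset -= t0
    return Session(trk, EventLog(ev_table), pho, geometry or Geometry())
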