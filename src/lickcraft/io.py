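"""Table I/O for the three data streams the pipeline touches.

Three plain-CSV formats are supported:

* event streams — timestamped beam-break intervals from the lickometer
  (``channel,onset_s,offset_s``);
* pose tracks — per-frame tongue/nose coordinates with a tracking
  likelihood, either as a flat table or in the DeepLabCut three-row-header
  dialect;
* two-channel photometry traces (``time_s,ch470,ch415``).

All timestamps are seconds as floats, 0-based and session-relative;
event intervals are closed ``[onset, offset]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "LickEvent",
    "EventStream",
    "BodypartTrack",
    "PoseTrack",
    "PhotometryTrace",
    "ParseError",
    "read_events",
    "write_events",
    "read_pose",
    "write_pose",
    "read_photometry",
    "write_photometry",
    "align_clocks",
]

_CHANNELS = ("lick", "nose")
POSE_BODYPARTS = ("nose", "tongue_tip")


class ParseError(ValueError):
    """Raised when an input table violates the format contract.

    The message always names the offending row (0-based data row index)
    so rejections are never silent.
    """


@dataclass(frozen=True, order=True)
class LickEvent:
    """A single beam-break interval on one detection channel."""

    onset: float
    offset: float
    channel: str = "lick"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.onset) and np.isfinite(self.offset)):
            raise ValueError(f"non-finite event timestamps ({self.onset}, {self.offset})")
        if self.offset <= self.onset:
            raise ValueError(
                f"event offset must exceed onset (got onset={self.onset}, offset={self.offset})"
            )
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {_CHANNELS}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class EventStream:
    """An ordered collection of beam-break events for one session.

    Events are kept sorted by onset; within a channel events must be
    strictly ordered and non-overlapping (closed intervals).
    """

    events: tuple[LickEvent, ...]
    session_id: str = ""
    clock: str = "session"

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: (e.onset, e.offset)))
        object.__setattr__(self, "events", events)
        for channel in _CHANNELS:
            prev = None
            for ev in events:
                if ev.channel != channel:
                    continue
                if prev is not None and ev.onset <= prev.offset:
                    raise ValueError(
                        f"overlapping events on channel {channel!r}: "
                        f"[{prev.onset}, {prev.offset}] then [{ev.onset}, {ev.offset}]"
                    )
                prev = ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def channel_events(self, channel: str = "lick") -> tuple[LickEvent, ...]:
        return tuple(e for e in self.events if e.channel == channel)

    def onsets(self, channel: str = "lick") -> np.ndarray:
        return np.array([e.onset for e in self.channel_events(channel)], dtype=float)

    def durations(self, channel: str = "lick") -> np.ndarray:
        return np.array([e.duration for e in self.channel_events(channel)], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": [e.channel for e in self.events],
                "onset_s": [e.onset for e in self.events],
                "offset_s": [e.offset for e in self.events],
            }
        )


@dataclass(frozen=True)
class BodypartTrack:
    """Per-frame coordinates and tracking likelihood for one bodypart.

    ``missing`` flags frames whose likelihood fell below the caller's
    threshold at read time; flagged frames are kept, never dropped.
    """

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.y) == len(self.likelihood) == len(self.missing) == n):
            raise ValueError("bodypart arrays must have equal length")
        lk = np.asarray(self.likelihood, dtype=float)
        if lk.size and (lk.min() < 0.0 or lk.max() > 1.0):
            raise ValueError("likelihood values must lie in [0, 1]")


@dataclass(frozen=True)
class PoseTrack:
    """A pose-tracking table sampled on a uniform frame grid."""

    frame_rate: float
    time: np.ndarray
    bodyparts: dict[str, BodypartTrack]

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        t = np.asarray(self.time, dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, 1.0 / self.frame_rate, rtol=0, atol=1e-6):
                raise ValueError("pose frames must be equally spaced at 1/frame_rate")
        unknown = set(self.bodyparts) - set(POSE_BODYPARTS)
        if unknown:
            raise ValueError(f"unknown bodyparts {sorted(unknown)}; expected {POSE_BODYPARTS}")
        for name, bp in self.bodyparts.items():
            if len(bp.x) != t.size:
                raise ValueError(f"bodypart {name!r} length differs from time axis")

    @property
    def n_frames(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class PhotometryTrace:
    """Two-channel fluorescence trace: 470 nm signal and 415 nm isosbestic."""

    rate: float
    time: np.ndarray
    ch470: np.ndarray
    ch415: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        t = np.asarray(self.time, dtype=float)
        if not (len(self.ch470) == len(self.ch415) == t.size):
            raise ValueError("time, ch470 and ch415 must have equal length")
        if t.size >= 2 and not np.allclose(np.diff(t), 1.0 / self.rate, rtol=0, atol=1e-6):
            raise ValueError("photometry trace must be uniformly sampled at `rate`")

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# event streams


def read_events(path) -> EventStream:
    """Read an event stream from CSV (columns ``channel,onset_s,offset_s``).

    Rows are sorted by onset on read. Malformed rows raise :class:`ParseError`
    naming the row; nothing is dropped silently.
    """
    df = pd.read_csv(path)
    required = {"channel", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s) {sorted(missing)} in {path}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            onset = float(row.onset_s)
            offset = float(row.offset_s)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {i}: non-numeric timestamp ({exc})") from exc
        try:
            events.append(LickEvent(onset=onset, offset=offset, channel=str(row.channel)))
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    try:
        return EventStream(events=tuple(events))
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_events(stream: EventStream, path) -> None:
    stream.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pose tracks

_PLAIN_POSE_COLUMNS = [
    "time_s",
    "nose_x",
    "nose_y",
    "nose_likelihood",
    "tongue_tip_x",
    "tongue_tip_y",
    "tongue_tip_likelihood",
]


def read_pose(path, dialect: str = "plain", likelihood_min: float = 0.0,
              frame_rate: float = 60.0) -> PoseTrack:
    """Read a pose-tracking table.

    Parameters
    ----------
    dialect
        ``"plain"`` — flat header with a ``time_s`` column and
        ``<bodypart>_{x,y,likelihood}`` triplets.
        ``"dlc"`` — DeepLabCut dialect: three header rows
        (scorer / bodyparts / coords) and a leading frame-index column;
        frame times are reconstructed as ``frame / frame_rate``.
    likelihood_min
        Frames with likelihood below this threshold are flagged
        ``missing`` (kept in the table, never dropped).
    frame_rate
        Only used by the ``dlc`` dialect, which carries no time column.
    """
    if dialect == "plain":
        df = pd.read_csv(path)
        missing_cols = set(_PLAIN_POSE_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ParseError(f"missing column(s) {sorted(missing_cols)} in {path}")
        if df[_PLAIN_POSE_COLUMNS].isna().any().any():
            bad = int(df[_PLAIN_POSE_COLUMNS].isna().any(axis=1).idxmax())
            raise ParseError(f"row {bad}: ragged or non-numeric pose row")
        time = df["time_s"].to_numpy(dtype=float)
        if time.size >= 2:
            frame_rate = 1.0 / float(np.median(np.diff(time)))
        data = {
            bp: {c: df[f"{bp}_{c}"].to_numpy(dtype=float) for c in ("x", "y", "likelihood")}
            for bp in POSE_BODYPARTS
        }
    elif dialect == "dlc":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
        if set(bodyparts) != set(POSE_BODYPARTS):
            raise ParseError(
                f"unknown bodypart set {sorted(bodyparts)}; expected {sorted(POSE_BODYPARTS)}"
            )
        if df.isna().any().any():
            bad = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
            raise ParseError(f"row {bad}: ragged or non-numeric pose row")
        scorer = df.columns[0][0]
        frames = df.index.to_numpy(dtype=float)
        time = frames / frame_rate
        data = {
            bp: {c: df[(scorer, bp, c)].to_numpy(dtype=float) for c in ("x", "y", "likelihood")}
            for bp in POSE_BODYPARTS
        }
    else:
        raise ValueError(f"unknown pose dialect {dialect!r}; expected 'plain' or 'dlc'")

    bodypart_tracks = {}
    for bp, cols in data.items():
        lk = cols["likelihood"]
        bodypart_tracks[bp] = BodypartTrack(
            x=cols["x"], y=cols["y"], likelihood=lk, missing=lk < likelihood_min
        )
    try:
        return PoseTrack(frame_rate=frame_rate, time=time, bodyparts=bodypart_tracks)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_pose(track: PoseTrack, path, dialect: str = "plain",
               scorer: str = "lickcraft") -> None:
    """Write a pose track to CSV (``plain`` by default; ``dlc`` provided as a
    convenience for fixtures and examples)."""
    if dialect == "plain":
        cols = {"time_s": track.time}
        for bp in POSE_BODYPARTS:
            t = track.bodyparts[bp]
            cols[f"{bp}_x"] = t.x
            cols[f"{bp}_y"] = t.y
            cols[f"{bp}_likelihood"] = t.likelihood
        pd.DataFrame(cols).to_csv(path, index=False)
    elif dialect == "dlc":
        columns = pd.MultiIndex.from_tuples(
            [(scorer, bp, c) for bp in POSE_BODYPARTS for c in ("x", "y", "likelihood")],
            names=["scorer", "bodyparts", "coords"],
        )
        values = np.column_stack(
            [getattr(track.bodyparts[bp], c) for bp in POSE_BODYPARTS for c in ("x", "y", "likelihood")]
        )
        df = pd.DataFrame(values, columns=columns)
        df.index.name = None
        df.to_csv(path, index=True)
    else:
        raise ValueError(f"unknown pose dialect {dialect!r}")


# ---------------------------------------------------------------------------
# photometry traces


def read_photometry(path) -> PhotometryTrace:
    """Read a two-channel trace from CSV (columns ``time_s,ch470,ch415``)."""
    df = pd.read_csv(path)
    required = {"time_s", "ch470", "ch415"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s) {sorted(missing)} in {path}")
    if df[list(required)].isna().any().any():
        bad = int(df[list(required)].isna().any(axis=1).idxmax())
        raise ParseError(f"row {bad}: non-numeric photometry sample")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise ParseError("photometry trace needs at least two samples")
    rate = 1.0 / float(np.median(np.diff(time)))
    try:
        return PhotometryTrace(
            rate=rate,
            time=time,
            ch470=df["ch470"].to_numpy(dtype=float),
            ch415=df["ch415"].to_numpy(dtype=float),
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_photometry(trace: PhotometryTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "ch470": trace.ch470, "ch415": trace.ch415}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clock alignment


def align_clocks(obj, offset: float):
    """Shift every timestamp of a stream/track/trace by a constant offset.

    Ordering is preserved. A shift that produces negative session time
    emits a warning rather than an error (the caller may be aligning onto
    a later-starting clock).
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    if isinstance(obj, EventStream):
        events = tuple(
            LickEvent(onset=e.onset + offset, offset=e.offset + offset, channel=e.channel)
            for e in obj.events
        )
        if any(e.onset < 0 for e in events):
            warnings.warn("clock alignment produced negative session times", stacklevel=2)
        return replace(obj, events=events)
    if isinstance(obj, PoseTrack):
        time = np.asarray(obj.time, dtype=float) + offset
        if time.size and time[0] < 0:
            warnings.warn("clock alignment produced negative session times", stacklevel=2)
        return replace(obj, time=time)
    if isinstance(obj, PhotometryTrace):
        time = np.asarray(obj.time, dtype=float) + offset
        if time.size and time[0] < 0:
            warnings.warn("clock alignment produced negative session times", stacklevel=2)
        return replace(obj, time=time)
    raise TypeError(f"cannot align object of type {type(obj).__name__}")
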