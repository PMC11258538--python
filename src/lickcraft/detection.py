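"""Validation of sensor lick detection against video ground truth.

The reference standard is the set of tongue protrusions visible on
bottom-view video: pose-derived displacement excursions past the poke
opening, typed as "short" (never reach the sipper) or "sipper". Sensor
events are matched to these video licks — the first event whose onset
falls inside a lick is its true positive, later events inside the same
lick and events outside every lick are false positives, and licks with
no event are false negatives. From the match come precision/recall, a
lick-kind × detected/missed contingency with an exact Fisher test, and
a post hoc artifact filter keeping events with plausible duration
(0.003–0.2 s) and interlick interval (> 0.05 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .io import EventStream, LickEvent, PoseTrack

__all__ = [
    "SegmentationConfig",
    "VideoLick",
    "MatchResult",
    "DetectionMetrics",
    "GroupedMetrics",
    "ContingencyTable2x2",
    "FilterConfig",
    "FilterRemoval",
    "segment_video_licks",
    "match_events",
    "detection_metrics",
    "fn_contingency",
    "fisher_exact_2x2",
    "apply_posthoc_filter",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds turning a pose track into video licks.

    A frame is part of a protrusion when tongue-tip likelihood is at
    least ``likelihood_min`` and displacement exceeds ``poke_line``;
    gaps of up to ``max_gap_frames`` below-threshold frames are
    tolerated inside one lick. A lick whose peak displacement reaches
    ``sipper_line`` is a "sipper" lick, otherwise "short".
    """

    likelihood_min: float = 0.9
    poke_line: float = 5.0
    sipper_line: float = 12.0
    max_gap_frames: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.likelihood_min <= 1.0):
            raise ValueError("likelihood_min must lie in [0, 1]")
        if self.sipper_line <= self.poke_line:
            raise ValueError("sipper_line must lie strictly beyond poke_line")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be non-negative")


@dataclass(frozen=True)
class VideoLick:
    """A video-determined tongue protrusion (the ground-truth unit)."""

    start: float
    end: float
    kind: str  # "short" | "sipper"
    peak_displacement: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("video lick end must exceed start")
        if self.kind not in ("short", "sipper"):
            raise ValueError(f"unknown lick kind {self.kind!r}")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching sensor events against video licks.

    ``event_labels[i]`` is ``"TP"`` or ``"FP"`` for event ``i`` (lick
    channel, stream order); ``lick_matched[j]`` says whether video lick
    ``j`` received an event (otherwise it is a false negative);
    ``assignment[i]`` is the index of the lick containing event ``i``
    (``None`` for events outside every lick).
    """

    event_labels: tuple[str, ...]
    lick_matched: tuple[bool, ...]
    assignment: tuple[int | None, ...]
    licks: tuple[VideoLick, ...]

    @property
    def tp(self) -> int:
        return sum(1 for l in self.event_labels if l == "TP")

    @property
    def fp(self) -> int:
        return sum(1 for l in self.event_labels if l == "FP")

    @property
    def fn(self) -> int:
        return sum(1 for m in self.lick_matched if not m)


def segment_video_licks(track: PoseTrack, cfg: SegmentationConfig) -> list[VideoLick]:
    """Segment video licks from the tongue-tip trajectory.

    Maximal runs of frames that are confidently tracked
    (likelihood ≥ ``likelihood_min``, not flagged missing) and displaced
    past ``poke_line`` become licks; runs separated by at most
    ``max_gap_frames`` sub-threshold frames are merged. Bounds are
    frame-accurate: ``start`` is the first active frame time, ``end`` the
    last active frame time plus one frame period.
    """
    if "tongue_tip" not in track.bodyparts:
        raise ValueError("pose track lacks a tongue_tip bodypart")
    bp = track.bodyparts["tongue_tip"]
    active = (
        (np.asarray(bp.likelihood) >= cfg.likelihood_min)
        & ~np.asarray(bp.missing, dtype=bool)
        & (np.asarray(bp.y, dtype=float) > cfg.poke_line)
    )
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    # merge runs separated by gaps <= max_gap_frames
    breaks = np.flatnonzero(np.diff(idx) > cfg.max_gap_frames + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    dt = 1.0 / track.frame_rate
    licks = []
    for s, e in zip(starts, ends):
        frames = idx[s : e + 1]
        peak = float(np.max(np.asarray(bp.y, dtype=float)[frames]))
        kind = "sipper" if peak >= cfg.sipper_line else "short"
        licks.append(
            VideoLick(
                start=float(track.time[frames[0]]),
                end=float(track.time[frames[-1]] + dt),
                kind=kind,
                peak_displacement=peak,
            )
        )
    return licks


def match_events(licks: Sequence[VideoLick], stream: EventStream) -> MatchResult:
    """Classify sensor events against video licks.

    An event belongs to the lick whose ``[start, end]`` interval contains
    its *onset* (a single unambiguous rule for events straddling a
    boundary). The first event in each lick is its true positive; any
    later event in the same lick, and any event in no lick, is a false
    positive. Licks that receive no event are false negatives.
    Overlapping video licks are rejected — assignment would be ambiguous.
    """
    licks = sorted(licks, key=lambda l: l.start)
    for a, b in zip(licks, licks[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping video licks [{a.start}, {a.end}] and [{b.start}, {b.end}]"
            )
    starts = np.array([l.start for l in licks], dtype=float)
    ends = np.array([l.end for l in licks], dtype=float)
    events = stream.channel_events("lick")
    labels: list[str] = []
    assignment: list[int | None] = []
    matched = [False] * len(licks)
    for ev in events:
        j = int(np.searchsorted(starts, ev.onset, side="right")) - 1
        if j >= 0 and ev.onset <= ends[j]:
            assignment.append(j)
            if matched[j]:
                labels.append("FP")
            else:
                matched[j] = True
                labels.append("TP")
        else:
            assignment.append(None)
            labels.append("FP")
    return MatchResult(
        event_labels=tuple(labels),
        lick_matched=tuple(matched),
        assignment=tuple(assignment),
        licks=tuple(licks),
    )


@dataclass(frozen=True)
class DetectionMetrics:
    """TP/FN/FP counts with the derived precision and recall.

    ``precision``/``recall`` are ``None`` (an explicit sentinel, never 0)
    when their denominator is empty.
    """

    tp: int
    fn: int
    fp: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None


@dataclass(frozen=True)
class GroupedMetrics:
    """Pooled counts plus per-session ratios and their mean ± sem.

    Pooled precision (ratio of summed counts) and the mean of
    per-session precisions differ in general; validation studies that
    report "precision ± sem over mice" use the latter, so both are kept.
    """

    pooled: DetectionMetrics
    per_session: tuple[DetectionMetrics, ...]

    def _stat(self, name: str) -> tuple[float | None, float | None]:
        vals = [getattr(m, name) for m in self.per_session]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None, None
        mean = float(np.mean(vals))
        sem = float(stats.sem(vals)) if len(vals) > 1 else 0.0
        return mean, sem

    @property
    def precision_mean_sem(self) -> tuple[float | None, float | None]:
        return self._stat("precision")

    @property
    def recall_mean_sem(self) -> tuple[float | None, float | None]:
        return self._stat("recall")


def detection_metrics(
    matches: MatchResult | Sequence[MatchResult],
) -> DetectionMetrics | GroupedMetrics:
    """Counts and ratios from one match, or pooled + per-session from many."""
    if isinstance(matches, MatchResult):
        return DetectionMetrics(tp=matches.tp, fn=matches.fn, fp=matches.fp)
    per = tuple(DetectionMetrics(tp=m.tp, fn=m.fn, fp=m.fp) for m in matches)
    pooled = DetectionMetrics(
        tp=sum(m.tp for m in per), fn=sum(m.fn for m in per), fp=sum(m.fp for m in per)
    )
    return GroupedMetrics(pooled=pooled, per_session=per)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2×2 test; rows are lick kinds, columns missed/detected."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")


def fn_contingency(matches: MatchResult | Sequence[MatchResult]) -> ContingencyTable2x2:
    """Tabulate false negatives by lick kind (short row, sipper row)."""
    if isinstance(matches, MatchResult):
        matches = [matches]
    counts = {("short", False): 0, ("short", True): 0, ("sipper", False): 0, ("sipper", True): 0}
    for m in matches:
        for lick, ok in zip(m.licks, m.lick_matched):
            counts[(lick.kind, ok)] += 1
    return ContingencyTable2x2(
        a=counts[("short", False)],
        b=counts[("short", True)],
        c=counts[("sipper", False)],
        d=counts[("sipper", True)],
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact test p-value for a 2×2 table.

    Computed with exact integer arithmetic: under fixed margins the
    hypergeometric probabilities share the denominator ``C(N, a+c)``, so
    tables are compared by their integer weights
    ``C(r1, a')·C(r2, c')`` and the two-sided p sums every table whose
    probability does not exceed the observed one (the "probability ≤
    observed" convention). Exactness matters: float tie-breaking can
    misclassify near-equal tables.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {ap: math.comb(r1, ap) * math.comb(r2, c1 - ap) for ap in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, math.comb(n, c1)))


@dataclass(frozen=True)
class FilterConfig:
    """The post hoc artifact filter's keep-window.

    Events are kept when their duration lies in ``[dur_min, dur_max]``
    and their interlick interval (onset-to-onset against the previous
    *kept* event) exceeds ``ili_min``; see :func:`apply_posthoc_filter`
    for the either/both interpretation switch.
    """

    dur_min: float = 0.003
    dur_max: float = 0.2
    ili_min: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.dur_min < self.dur_max):
            raise ValueError("require 0 < dur_min < dur_max")
        if self.ili_min <= 0:
            raise ValueError("ili_min must be positive")


@dataclass(frozen=True)
class FilterRemoval:
    """One removed event with the criterion that fired."""

    event: LickEvent
    reason: str  # "duration" | "ili" | "duration+ili"


def apply_posthoc_filter(
    stream: EventStream, cfg: FilterConfig, mode: str = "conjunctive"
) -> tuple[EventStream, list[FilterRemoval]]:
    """Apply the duration/ILI artifact filter to the lick channel.

    ``mode="conjunctive"`` (default) keeps an event only when *both*
    criteria pass: duration inside the window and ILI above threshold
    (or no preceding kept event). ``mode="disjunctive"`` keeps an event
    when *either* passes, removing only events failing both — the other
    reading of an "and/or" inclusion rule. The ILI is always measured
    against the previous **kept** event, so a removed double-detection
    cannot shield the next one. Non-lick channels pass through untouched.
    """
    if mode not in ("conjunctive", "disjunctive"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept: list[LickEvent] = []
    removals: list[FilterRemoval] = []
    last_kept_onset: float | None = None
    for ev in stream.channel_events("lick"):
        dur_ok = cfg.dur_min <= ev.duration <= cfg.dur_max
        ili_ok = last_kept_onset is None or (ev.onset - last_kept_onset) > cfg.ili_min
        keep = (dur_ok and ili_ok) if mode == "conjunctive" else (dur_ok or ili_ok)
        if keep:
            kept.append(ev)
            last_kept_onset = ev.onset
        else:
            reason = "+".join(
                r for r, bad in (("duration", not dur_ok), ("ili", not ili_ok)) if bad
            )
            removals.append(FilterRemoval(event=ev, reason=reason))
    other = [e for e in stream.events if e.channel != "lick"]
    filtered = EventStream(
        events=tuple(sorted(kept + other, key=lambda e: e.onset)),
        session_id=stream.session_id,
        clock=stream.clock,
    )
    return filtered, removals
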