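"""Synthetic sessions with known ground truth.

This module emulates the data a head-free mouse produces at an optical
lickometer during a bout-triggered reward task, together with the two
measurement channels used to validate the device:

* **lick trains** — bouts of rhythmic licking whose within-bout
  interlick intervals concentrate near 0.146 s, the within-bout rhythm
  observed in mice licking a recessed sipper;
* **sensor corruption** — the lickometer's documented error processes:
  false negatives concentrated in "short" licks (tongue protrusions that
  do not reach the sipper), occasional double-detections within a single
  lick (a second event < 0.05 s after the first) and long beam breaks
  caused by the snout while exploring;
* **task structure** — 5 µl rewards delivered on the first lick of a
  bout, gated by an exponential intertrial interval with mean 18 s
  truncated to [2, 30] s;
* **pose tracks** — a 60 Hz tongue/nose tracking table mirroring what a
  markerless tracker produces from bottom-view video;
* **photometry** — a 50 Hz two-channel fluorescence trace with slow
  two-exponential bleaching, shot noise, positive dopamine-like
  transients at rewarded first licks and dips at unrewarded first licks,
  plus an isosbestic channel that shares the bleach but carries no
  lick-locked signal.

Every generator takes a ``numpy.random.Generator``; fixing the seed fixes
every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import BodypartTrack, EventStream, LickEvent, PhotometryTrace, PoseTrack

__all__ = [
    "TaskConfig",
    "CountDistribution",
    "Uniform",
    "LickTrainParams",
    "ErrorModel",
    "Lick",
    "GroundTruthSession",
    "CorruptionResult",
    "PhotoSimConfig",
    "PoseSimConfig",
    "sample_iti",
    "truncated_exponential_mean",
    "truncated_exponential_cdf",
    "generate_lick_train",
    "simulate_task_session",
    "corrupt_events",
    "synthesize_pose",
    "simulate_photometry",
    "transient_peak_offset",
]


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class TaskConfig:
    """Reward-scheduling parameters of the bout-triggered licking task.

    ``iti_mean`` is the mean of the *untruncated* exponential from which
    intertrial intervals are drawn; draws are conditioned on
    ``[iti_min, iti_max]`` by rejection, so the effective mean is lower
    (≈ 12.51 s at the defaults).
    """

    iti_mean: float = 18.0
    iti_min: float = 2.0
    iti_max: float = 30.0
    reward_volume_ul: float = 5.0  # metadata only
    session_duration: float = 1800.0

    def __post_init__(self) -> None:
        # equal bounds are allowed as a degenerate (deterministic) interval
        if not (0 < self.iti_min <= self.iti_max):
            raise ValueError("require 0 < iti_min <= iti_max")
        if self.iti_mean <= 0:
            raise ValueError("iti_mean must be positive")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")


@dataclass(frozen=True)
class CountDistribution:
    """A named discrete distribution for licks per bout.

    Supported names: ``fixed`` (params: n), ``poisson`` (params: mu),
    ``geometric`` (params: p; support 1, 2, ...). Draws are floored at 1
    — a bout has at least one lick by definition.
    """

    name: str = "poisson"
    params: dict = field(default_factory=lambda: {"mu": 12.0})

    def __post_init__(self) -> None:
        if self.name not in ("fixed", "poisson", "geometric"):
            raise ValueError(f"unknown count distribution {self.name!r}")

    def sample(self, rng: np.random.Generator) -> int:
        if self.name == "fixed":
            return max(1, int(self.params["n"]))
        if self.name == "poisson":
            return max(1, int(rng.poisson(self.params["mu"])))
        return max(1, int(rng.geometric(self.params["p"])))


@dataclass(frozen=True)
class Uniform:
    """A uniform interval spec used for artifact gap/duration draws."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ValueError("require lo < hi")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.lo, self.hi, size=size)


@dataclass(frozen=True)
class LickTrainParams:
    """Shape of the generated licking behavior.

    Within-bout interlick intervals are truncated-normal with floor
    ``ili_floor``; lick durations are truncated-normal inside
    ``[lick_duration_min, lick_duration_max]`` — the same window the
    post hoc artifact filter keeps, so a clean true lick is never
    filtered. ``p_short`` is the probability a lick is a "short" lick
    (fails to reach the sipper); the default reproduces the 27/230 share
    seen in validation recordings.
    """

    bout_rate: float = 0.08  # bouts per second of free time
    licks_per_bout: CountDistribution = field(default_factory=CountDistribution)
    ili_mean: float = 0.146
    ili_sd: float = 0.015
    ili_floor: float = 0.05
    lick_duration_mean: float = 0.06
    lick_duration_sd: float = 0.02
    lick_duration_min: float = 0.003
    lick_duration_max: float = 0.2
    p_short: float = 27.0 / 230.0

    def __post_init__(self) -> None:
        if self.bout_rate <= 0:
            raise ValueError("bout_rate must be positive")
        if self.ili_floor <= 0:
            raise ValueError("ili_floor must be positive")
        if self.ili_mean <= self.ili_floor:
            raise ValueError("ili_mean must exceed ili_floor")
        if self.ili_sd <= 0 or self.lick_duration_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not (0 < self.lick_duration_min < self.lick_duration_max):
            raise ValueError("require 0 < lick_duration_min < lick_duration_max")
        if not (0.0 <= self.p_short <= 1.0):
            raise ValueError("p_short must be a probability")


@dataclass(frozen=True)
class ErrorModel:
    """Sensor error processes of the optical lickometer.

    False-negative probabilities default to the validation-study rates
    (10/27 for short licks, 4/203 for sipper licks). False positives come
    in two flavors: *double detections* — a second event < 0.05 s after a
    true event within the same lick — and *snout artifacts* — beam breaks
    outside any lick, mostly long (duration above the 0.2 s filter
    ceiling). ``snout_guard`` keeps artifacts clear of true lick events
    by at least that margin, so an artifact can never mask a true lick.
    """

    p_fn_short: float = 10.0 / 27.0
    p_fn_sipper: float = 4.0 / 203.0
    p_double: float = 0.06
    double_gap: Uniform = field(default_factory=lambda: Uniform(0.006, 0.045))
    p_snout: float = 0.033  # artifacts per second of session
    snout_duration: Uniform = field(default_factory=lambda: Uniform(0.08, 0.6))
    snout_guard: float = 0.055

    def __post_init__(self) -> None:
        for name in ("p_fn_short", "p_fn_sipper", "p_double"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_snout < 0:
            raise ValueError("p_snout must be non-negative")
        if not (0 < self.double_gap.lo and self.double_gap.hi < 0.05):
            raise ValueError("double_gap support must lie inside (0, 0.05)")
        if self.snout_guard <= 0.05:
            raise ValueError("snout_guard must exceed the 0.05 s ILI filter threshold")


@dataclass(frozen=True)
class Lick:
    """One ground-truth tongue protrusion."""

    onset: float
    offset: float
    kind: str  # "short" | "sipper"
    bout_index: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class GroundTruthSession:
    """Simulated truth: licks with bout labels, bout index ranges, rewards."""

    licks: tuple[Lick, ...]
    bouts: tuple[tuple[int, int], ...]  # (first_lick_index, last_lick_index) inclusive
    reward_times: tuple[float, ...]
    duration: float

    def __post_init__(self) -> None:
        prev = None
        for lk in self.licks:
            if lk.offset <= lk.onset:
                raise ValueError("lick offset must exceed onset")
            if prev is not None and lk.onset <= prev.offset:
                raise ValueError("licks must be strictly ordered and non-overlapping")
            prev = lk
        first_onsets = {self.licks[b[0]].onset for b in self.bouts}
        for rt in self.reward_times:
            if rt not in first_onsets:
                raise ValueError("every reward must coincide with a bout's first lick")

    @property
    def n_licks(self) -> int:
        return len(self.licks)

    @property
    def n_rewards(self) -> int:
        return len(self.reward_times)

    def bout_first_lick_times(self) -> np.ndarray:
        return np.array([self.licks[b[0]].onset for b in self.bouts], dtype=float)

    def unrewarded_first_lick_times(self) -> np.ndarray:
        rewarded = set(self.reward_times)
        return np.array(
            [t for t in self.bout_first_lick_times() if t not in rewarded], dtype=float
        )

    def within_bout_ilis(self) -> np.ndarray:
        """Onset-to-onset intervals between consecutive licks of the same bout."""
        out = []
        onsets = [lk.onset for lk in self.licks]
        for first, last in self.bouts:
            out.extend(np.diff(onsets[first : last + 1]))
        return np.asarray(out, dtype=float)

    def lick_onsets(self) -> np.ndarray:
        return np.array([lk.onset for lk in self.licks], dtype=float)


# ---------------------------------------------------------------------------
# intertrial intervals


def truncated_exponential_mean(config: TaskConfig) -> float:
    """Closed-form mean of Exp(iti_mean) conditioned on [iti_min, iti_max].

    With rate λ = 1/iti_mean and span Δ = iti_max − iti_min the
    conditional mean is ``a + 1/λ − Δ·e^{−λΔ}/(1 − e^{−λΔ})``.
    """
    lam = 1.0 / config.iti_mean
    delta = config.iti_max - config.iti_min
    if delta == 0:
        return config.iti_min
    return config.iti_min + 1.0 / lam - delta * math.exp(-lam * delta) / (
        1.0 - math.exp(-lam * delta)
    )


def truncated_exponential_cdf(x, config: TaskConfig):
    """CDF of the conditional (truncated) ITI distribution, vectorized."""
    lam = 1.0 / config.iti_mean
    x = np.asarray(x, dtype=float)
    num = 1.0 - np.exp(-lam * np.clip(x - config.iti_min, 0.0, None))
    den = 1.0 - math.exp(-lam * (config.iti_max - config.iti_min))
    return np.where(x >= config.iti_max, 1.0, num / den)


def sample_iti(config: TaskConfig, rng: np.random.Generator, size=None):
    """Draw intertrial interval(s) by rejection from Exp(iti_mean) onto
    [iti_min, iti_max] (the conditional distribution, not a clamp)."""
    if config.iti_min == config.iti_max:  # degenerate interval
        return (
            config.iti_min if size is None else np.full(size, config.iti_min, dtype=float)
        )
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        draws = rng.exponential(config.iti_mean, size=max(2 * (n - filled), 16))
        ok = draws[(draws >= config.iti_min) & (draws <= config.iti_max)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return float(out[0]) if scalar else out.reshape(size)


# ---------------------------------------------------------------------------
# lick trains


def _truncnorm(rng, mean, sd, lo, hi, size):
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_lick_train(
    params: LickTrainParams,
    duration: float,
    rng: np.random.Generator,
    bout_break: float = 0.5,
) -> GroundTruthSession:
    """Generate a bout-structured lick train with no rewards attached.

    Bout onsets follow a homogeneous Poisson process on free time with an
    enforced minimum inter-bout gap equal to ``bout_break``, so bout labels
    here agree exactly with analysis-side bout segmentation at the same
    threshold. Within-bout intervals are truncated-normal
    (``ili_mean``, ``ili_sd``) floored at ``ili_floor``; lick durations are
    truncated-normal inside the artifact filter's keep-window and clipped
    below the next interval so licks never overlap.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    licks: list[Lick] = []
    bouts: list[tuple[int, int]] = []
    t = rng.exponential(1.0 / params.bout_rate)
    bout_index = 0
    while t < duration:
        n = params.licks_per_bout.sample(rng)
        ilis = _truncnorm(rng, params.ili_mean, params.ili_sd, params.ili_floor, np.inf, n - 1)
        durs = _truncnorm(
            rng,
            params.lick_duration_mean,
            params.lick_duration_sd,
            params.lick_duration_min,
            params.lick_duration_max,
            n,
        )
        onsets = t + np.concatenate([[0.0], np.cumsum(ilis)])
        first = len(licks)
        for i in range(n):
            dur = durs[i]
            if i < n - 1:
                dur = min(dur, ilis[i] - 1e-3)  # keep licks disjoint
            dur = max(dur, params.lick_duration_min)
            onset = float(onsets[i])
            offset = onset + float(dur)
            if offset > duration:
                break
            kind = "short" if rng.random() < params.p_short else "sipper"
            licks.append(Lick(onset=onset, offset=offset, kind=kind, bout_index=bout_index))
        if len(licks) > first:
            bouts.append((first, len(licks) - 1))
            bout_index += 1
            last_off = licks[-1].offset
        else:
            last_off = t
        t = last_off + bout_break + rng.exponential(1.0 / params.bout_rate)
    return GroundTruthSession(
        licks=tuple(licks), bouts=tuple(bouts), reward_times=(), duration=float(duration)
    )


def simulate_task_session(
    task: TaskConfig,
    params: LickTrainParams,
    rng: np.random.Generator,
    bout_break: float = 0.5,
) -> GroundTruthSession:
    """Simulate a full task session: lick train plus bout-triggered rewards.

    Reward scheduling is a small state machine: an availability clock is
    armed with a truncated-exponential ITI; the first lick of the first
    bout starting at or after availability triggers a reward and re-arms
    the clock from the reward time. Bouts starting earlier are unrewarded
    and do not touch the clock.
    """
    train = generate_lick_train(params, task.session_duration, rng, bout_break=bout_break)
    reward_times = []
    available_at = sample_iti(task, rng)
    for first, _last in train.bouts:
        t0 = train.licks[first].onset
        if t0 >= available_at:
            reward_times.append(t0)
            available_at = t0 + sample_iti(task, rng)
    return GroundTruthSession(
        licks=train.licks,
        bouts=train.bouts,
        reward_times=tuple(reward_times),
        duration=train.duration,
    )


# ---------------------------------------------------------------------------
# sensor corruption


@dataclass(frozen=True)
class CorruptionResult:
    """A corrupted sensor stream with per-event provenance.

    ``labels[i]`` is one of ``"true"``, ``"double_fp"``, ``"snout_fp"``
    for ``stream.events[i]``; ``dropped[j]`` flags ground-truth lick ``j``
    as a sensor false negative.
    """

    stream: EventStream
    labels: tuple[str, ...]
    dropped: tuple[bool, ...]


def corrupt_events(
    truth: GroundTruthSession, model: ErrorModel, rng: np.random.Generator
) -> CorruptionResult:
    """Apply the sensor error model to a ground-truth session.

    Each short lick is dropped with ``p_fn_short`` and each sipper lick
    with ``p_fn_sipper``. A surviving lick normally emits one event
    spanning the lick; with probability ``p_double`` it instead emits two
    events separated by a gap drawn from ``double_gap`` (< 0.05 s, the
    double-detection signature). Snout artifacts are placed uniformly over
    artifact-free time at rate ``p_snout`` per second, never closer than
    ``snout_guard`` to any true event.
    """
    raw: list[tuple[float, float, str]] = []
    dropped: list[bool] = []
    n = truth.n_licks
    onsets = truth.lick_onsets()
    for j, lk in enumerate(truth.licks):
        p_fn = model.p_fn_short if lk.kind == "short" else model.p_fn_sipper
        if rng.random() < p_fn:
            dropped.append(True)
            continue
        dropped.append(False)
        next_onset = onsets[j + 1] if j + 1 < n else truth.duration + 1.0
        if rng.random() < model.p_double:
            g = float(model.double_gap.sample(rng))
            first_off = lk.onset + max(g - 0.002, 0.004)
            raw.append((lk.onset, first_off, "true"))
            d_on = lk.onset + g
            # always emitted: the gap to the next true onset is >= ili_floor - g
            d_off = min(d_on + 0.008, next_onset - 1e-3)
            raw.append((d_on, d_off, "double_fp"))
        else:
            raw.append((lk.onset, min(lk.offset, next_onset - 1e-3), "true"))

    # snout artifacts: Poisson count, uniform placement with rejection
    guarded = [
        (lk.onset - model.snout_guard, lk.offset + model.snout_guard) for lk in truth.licks
    ]
    n_snout = rng.poisson(model.p_snout * truth.duration)
    placed: list[tuple[float, float]] = []
    for _ in range(n_snout):
        for _attempt in range(100):
            d = float(model.snout_duration.sample(rng))
            if d >= truth.duration:
                continue
            on = rng.uniform(0.0, truth.duration - d)
            off = on + d
            clash = any(on < g_off and off > g_on for g_on, g_off in guarded)
            clash = clash or any(on <= p_off and off >= p_on for p_on, p_off in placed)
            if not clash:
                placed.append((on, off))
                raw.append((on, off, "snout_fp"))
                break
    raw.sort(key=lambda r: r[0])
    events = tuple(LickEvent(onset=on, offset=off, channel="lick") for on, off, _ in raw)
    labels = tuple(lbl for _, _, lbl in raw)
    return CorruptionResult(
        stream=EventStream(events=events), labels=labels, dropped=tuple(dropped)
    )


# ---------------------------------------------------------------------------
# pose synthesis


@dataclass(frozen=True)
class PoseSimConfig:
    """Geometry and noise of the synthesized 60 Hz pose track.

    Displacement is the tongue-tip coordinate along the poke axis
    (pixels); ``poke_line`` marks a detectable protrusion and
    ``sipper_line`` the sipper position (~1.2 mm behind the light path).
    Short licks peak between the two lines, sipper licks beyond the
    sipper line.
    """

    frame_rate: float = 60.0
    poke_line: float = 5.0
    sipper_line: float = 12.0
    short_peak: Uniform = field(default_factory=lambda: Uniform(6.0, 10.0))
    sipper_peak: Uniform = field(default_factory=lambda: Uniform(13.0, 18.0))
    baseline_noise_sd: float = 0.3
    lick_likelihood: float = 0.99
    idle_likelihood: Uniform = field(default_factory=lambda: Uniform(0.05, 0.4))

    def __post_init__(self) -> None:
        if self.sipper_line <= self.poke_line:
            raise ValueError("sipper_line must lie beyond poke_line")
        if not (self.poke_line < self.short_peak.lo and self.short_peak.hi < self.sipper_line):
            raise ValueError("short_peak support must lie between poke_line and sipper_line")
        if self.sipper_peak.lo < self.sipper_line:
            raise ValueError("sipper_peak support must lie beyond sipper_line")


def synthesize_pose(
    truth: GroundTruthSession, cfg: PoseSimConfig, rng: np.random.Generator
) -> PoseTrack:
    """Render a ground-truth session as a pose-tracking table.

    Each lick becomes a rectangular displacement pulse on the frame grid
    with ≥ 1 active frame and ≥ 2 inactive frames between consecutive
    licks (boundary frames are trimmed when licks crowd), so that
    threshold-based segmentation recovers lick count and kind exactly and
    bounds to within one frame.
    """
    dt = 1.0 / cfg.frame_rate
    n_frames = int(np.floor(truth.duration / dt)) + 1
    time = np.arange(n_frames) * dt

    y = rng.normal(0.0, cfg.baseline_noise_sd, size=n_frames)
    lik = cfg.idle_likelihood.sample(rng, size=n_frames)
    x = rng.normal(0.0, cfg.baseline_noise_sd, size=n_frames)

    # frame window per lick: frames with time in [onset - dt, offset] — always >= 1
    windows: list[list[int]] = []
    for lk in truth.licks:
        lo = max(0, int(np.ceil((lk.onset - dt) / dt - 1e-9)))
        hi = min(n_frames - 1, int(np.floor(lk.offset / dt + 1e-9)))
        if hi < lo:  # no grid point fell inside; take the nearest frame
            lo = hi = min(n_frames - 1, max(0, int(round((lk.onset + lk.offset) / 2 / dt))))
        windows.append([lo, hi])
    # enforce >= 2 inactive frames between consecutive licks (a 1-frame gap
    # would be bridged by gap-tolerant segmentation): shrink the earlier
    # window, then shift the later one, so every lick keeps >= 1 frame
    min_gap = 2
    for i in range(1, len(windows)):
        p, w = windows[i - 1], windows[i]
        need = p[1] + min_gap + 1
        if w[0] < need:
            p[1] = max(p[0], w[0] - min_gap - 1)
            need = p[1] + min_gap + 1
            w[0] = max(w[0], need)
            if w[1] < w[0]:
                w[1] = w[0]
    for lk, (lo, hi) in zip(truth.licks, windows):
        if lo >= n_frames:
            continue  # truncated at session end
        hi = min(hi, n_frames - 1)
        peak = (
            cfg.short_peak.sample(rng) if lk.kind == "short" else cfg.sipper_peak.sample(rng)
        )
        y[lo : hi + 1] = peak
        lik[lo : hi + 1] = cfg.lick_likelihood

    tongue = BodypartTrack(x=x, y=y, likelihood=lik, missing=np.zeros(n_frames, dtype=bool))
    nose_lik = np.clip(rng.normal(0.95, 0.02, size=n_frames), 0.0, 1.0)
    nose = BodypartTrack(
        x=rng.normal(0.0, 0.5, size=n_frames),
        y=rng.normal(-8.0, 0.5, size=n_frames),
        likelihood=nose_lik,
        missing=np.zeros(n_frames, dtype=bool),
    )
    return PoseTrack(
        frame_rate=cfg.frame_rate, time=time, bodyparts={"nose": nose, "tongue_tip": tongue}
    )


# ---------------------------------------------------------------------------
# photometry synthesis


@dataclass(frozen=True)
class PhotoSimConfig:
    """Parameters of the simulated two-channel fluorescence trace.

    The signal channel carries a two-exponential photobleaching decay,
    Gaussian noise, a positive transient kernel at each rewarded first
    lick and a negative (slower) dip kernel at each unrewarded first
    lick. The isosbestic channel shares the bleach shape (scaled by
    ``iso_scale``) and its own independent noise but no lick-locked
    kernel. Amplitudes are in arbitrary fluorescence units.
    """

    rate: float = 50.0
    baseline: float = 2.0
    bleach_amp1: float = 0.8
    bleach_tau1: float = 300.0
    bleach_amp2: float = 0.4
    bleach_tau2: float = 1200.0
    noise_sd: float = 0.02
    transient_amp: float = 0.2
    transient_rise: float = 0.05
    transient_decay: float = 0.4
    dip_amp: float = -0.1
    dip_rise: float = 0.2
    dip_decay: float = 0.8
    iso_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for name in ("bleach_tau1", "bleach_tau2", "transient_rise", "transient_decay",
                     "dip_rise", "dip_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.transient_amp < 0:
            raise ValueError("transient_amp must be non-negative (positive transients)")
        if self.dip_amp > 0:
            raise ValueError("dip_amp must be non-positive (negative deflections)")


def transient_peak_offset(rise: float, decay: float) -> float:
    """Time from event onset to the peak of the double-exponential kernel
    ``(1 − e^{−s/rise})·e^{−s/decay}``: ``rise·ln(1 + decay/rise)``."""
    return rise * math.log1p(decay / rise)


def _kernel(s: np.ndarray, amp: float, rise: float, decay: float) -> np.ndarray:
    """Double-exponential event kernel normalized so its peak equals ``amp``."""
    k = (1.0 - np.exp(-s / rise)) * np.exp(-s / decay)
    s_peak = transient_peak_offset(rise, decay)
    peak = (1.0 - math.exp(-s_peak / rise)) * math.exp(-s_peak / decay)
    return amp * k / peak


def _add_events(signal: np.ndarray, time: np.ndarray, events: np.ndarray,
                amp: float, rise: float, decay: float) -> None:
    rate = 1.0 / (time[1] - time[0]) if len(time) > 1 else 1.0
    span = int(np.ceil((rise + 8.0 * decay) * rate))
    for t0 in events:
        i0 = int(np.searchsorted(time, t0))
        i1 = min(len(time), i0 + span)
        if i0 >= len(time):
            continue
        s = time[i0:i1] - t0
        signal[i0:i1] += _kernel(np.clip(s, 0.0, None), amp, rise, decay)


def simulate_photometry(
    truth: GroundTruthSession, cfg: PhotoSimConfig, rng: np.random.Generator
) -> PhotometryTrace:
    """Render a session's reward structure as a two-channel trace.

    Requires reward annotations on ``truth`` (rewarded vs unrewarded
    first licks drive the transient/dip kernels).
    """
    n = int(np.floor(truth.duration * cfg.rate)) + 1
    time = np.arange(n) / cfg.rate
    bleach = (
        cfg.baseline
        + cfg.bleach_amp1 * np.exp(-time / cfg.bleach_tau1)
        + cfg.bleach_amp2 * np.exp(-time / cfg.bleach_tau2)
    )
    ch470 = bleach.copy()
    _add_events(ch470, time, np.asarray(truth.reward_times, dtype=float),
                cfg.transient_amp, cfg.transient_rise, cfg.transient_decay)
    _add_events(ch470, time, truth.unrewarded_first_lick_times(),
                cfg.dip_amp, cfg.dip_rise, cfg.dip_decay)
    if cfg.noise_sd > 0:
        ch470 = ch470 + rng.normal(0.0, cfg.noise_sd, size=n)
    ch415 = cfg.iso_scale * bleach
    if cfg.noise_sd > 0:
        ch415 = ch415 + rng.normal(0.0, cfg.noise_sd, size=n)
    return PhotometryTrace(rate=cfg.rate, time=time, ch470=ch470, ch415=ch415)
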