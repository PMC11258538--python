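"""Fiber-photometry processing: detrend, ΔF, z-score, PETHs, group test.

The processing chain for a two-channel (470 nm signal / 415 nm
isosbestic) fluorescence recording:

1. estimate the slow photobleaching trend of each channel with robust
   locally weighted regression (LOWESS; frac = 0.1, it = 3, delta = 20
   sample-index units by default) and subtract it;
2. subtract the detrended isosbestic channel from the detrended signal
   channel (ΔF), removing shared non-activity fluctuations;
3. z-score ΔF over the whole session (population SD);
4. extract peri-event time histograms (PETHs) around event onsets at
   nearest-sample alignment;
5. compare rewarded vs unrewarded PETHs across subjects with a two-way
   within-subjects (repeated-measures) ANOVA over time × trial type,
   plus per-timepoint paired post hoc tests giving a significance mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io import PhotometryTrace

__all__ = [
    "PhotometryConfig",
    "PethConfig",
    "PETH",
    "EffectResult",
    "AnovaResult",
    "lowess_smooth",
    "preprocess",
    "compute_peth",
    "subject_peth_matrix",
    "compare_peths",
]


@dataclass(frozen=True)
class PhotometryConfig:
    """LOWESS detrending parameters.

    ``lowess_frac`` — fraction of samples in each local fit window;
    ``lowess_it`` — robustifying (bisquare-reweighting) iterations;
    ``lowess_delta`` — sample-index distance within which local fits are
    linearly interpolated instead of recomputed (20 samples = 0.4 s at
    50 Hz).
    """

    lowess_frac: float = 0.1
    lowess_it: int = 3
    lowess_delta: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.lowess_frac <= 1):
            raise ValueError("lowess_frac must lie in (0, 1]")
        if self.lowess_it < 0:
            raise ValueError("lowess_it must be non-negative")
        if self.lowess_delta < 0:
            raise ValueError("lowess_delta must be non-negative")


def lowess_smooth(y: Sequence[float], cfg: PhotometryConfig | None = None) -> np.ndarray:
    """Robust locally weighted regression of a series against sample index.

    Cleveland-style LOWESS: at each anchor point a weighted linear fit
    over the nearest ``frac·n`` neighbors with tricube weights, followed
    by ``it`` robustifying passes that bisquare-downweight large
    residuals (scale 6·median|r|); points within ``delta`` index units
    of the last anchor are linearly interpolated. Returns the fitted
    (trend) series.
    """
    cfg = cfg or PhotometryConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    if int(cfg.lowess_frac * n) < 2:
        raise ValueError(
            f"lowess window has fewer than 2 points (frac={cfg.lowess_frac}, n={n})"
        )
    x = np.arange(n, dtype=float)
    return sm.nonparametric.lowess(
        y,
        x,
        frac=cfg.lowess_frac,
        it=cfg.lowess_it,
        delta=cfg.lowess_delta,
        is_sorted=True,
        return_sorted=False,
    )


def preprocess(
    trace: PhotometryTrace, cfg: PhotometryConfig | None = None, zscore: bool = True
) -> np.ndarray:
    """Detrend both channels, subtract isosbestic, optionally z-score.

    Returns the session-long ΔF series (z-scored by default with the
    population SD). A constant ΔF has no z-score and raises.
    """
    cfg = cfg or PhotometryConfig()
    resid470 = np.asarray(trace.ch470, dtype=float) - lowess_smooth(trace.ch470, cfg)
    resid415 = np.asarray(trace.ch415, dtype=float) - lowess_smooth(trace.ch415, cfg)
    df = resid470 - resid415
    if not zscore:
        return df
    sd = float(np.std(df))  # population (n) SD
    if sd == 0.0:
        raise ValueError("ΔF is constant; z-score undefined")
    return (df - float(np.mean(df))) / sd


@dataclass(frozen=True)
class PethConfig:
    """Peri-event window definition.

    The window spans ``[-window_pre, +window_post]`` seconds around each
    event onset; at the trace rate that is
    ``round(window_pre·rate) + round(window_post·rate) + 1`` samples
    (226 at the defaults and 50 Hz). ``baseline`` is an optional
    ``(lo, hi)`` interval (seconds, relative) whose per-trial mean is
    subtracted.
    """

    window_pre: float = 1.5
    window_post: float = 3.0
    n_timepoints: int | None = 226
    baseline: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.window_pre < 0 or self.window_post < 0:
            raise ValueError("window bounds must be non-negative")
        if self.window_pre + self.window_post <= 0:
            raise ValueError("window must have positive extent")


@dataclass(frozen=True)
class PETH:
    """Event-aligned trial matrix with its mean ± sem traces."""

    rel_time: np.ndarray
    trial_matrix: np.ndarray  # trials (or subjects) × timepoints
    group: str = ""

    @property
    def mean(self) -> np.ndarray:
        return self.trial_matrix.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        if self.trial_matrix.shape[0] < 2:
            return np.zeros(self.trial_matrix.shape[1])
        return stats.sem(self.trial_matrix, axis=0)

    @property
    def n_trials(self) -> int:
        return self.trial_matrix.shape[0]


def compute_peth(
    z: Sequence[float],
    event_times: Sequence[float],
    rate: float,
    cfg: PethConfig | None = None,
    group: str = "",
) -> tuple[PETH, list[float]]:
    """Extract the peri-event trial matrix around each event onset.

    Events are aligned at the nearest sample; events whose full window
    falls outside the session are dropped and returned in the second
    element so no trial disappears silently. Raises when no usable event
    remains.
    """
    cfg = cfg or PethConfig()
    z = np.asarray(z, dtype=float)
    n_pre = int(round(cfg.window_pre * rate))
    n_post = int(round(cfg.window_post * rate))
    n_t = n_pre + n_post + 1
    if cfg.n_timepoints is not None and cfg.n_timepoints != n_t:
        raise ValueError(
            f"window spans {n_t} samples at rate {rate} Hz but n_timepoints={cfg.n_timepoints}"
        )
    rel_time = np.arange(-n_pre, n_post + 1) / rate
    rows, dropped = [], []
    for t in np.asarray(event_times, dtype=float):
        i0 = int(round(t * rate))
        if i0 - n_pre < 0 or i0 + n_post >= z.size:
            dropped.append(float(t))
            continue
        rows.append(z[i0 - n_pre : i0 + n_post + 1])
    if not rows:
        raise ValueError("no event with a full peri-event window inside the session")
    mat = np.asarray(rows, dtype=float)
    if cfg.baseline is not None:
        lo, hi = cfg.baseline
        sel = (rel_time >= lo) & (rel_time <= hi)
        if not sel.any():
            raise ValueError("baseline interval contains no timepoints")
        mat = mat - mat[:, sel].mean(axis=1, keepdims=True)
    return PETH(rel_time=rel_time, trial_matrix=mat, group=group), dropped


def subject_peth_matrix(peths: Sequence[PETH], group: str = "") -> PETH:
    """Stack per-subject mean traces into a subjects × timepoints PETH."""
    if not peths:
        raise ValueError("no subject PETHs given")
    rel = peths[0].rel_time
    for p in peths[1:]:
        if p.rel_time.shape != rel.shape or not np.allclose(p.rel_time, rel):
            raise ValueError("subject PETHs have mismatched time axes")
    return PETH(rel_time=rel, trial_matrix=np.vstack([p.mean for p in peths]), group=group)


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Two-way within-subjects ANOVA over time × trial type.

    ``posthoc_p`` holds per-timepoint paired-comparison p-values after
    multiple-comparison correction; ``sig_mask`` flags timepoints where
    the corrected p falls below ``alpha`` (the shaded-significance-window
    analogue).
    """

    time: EffectResult
    trial_type: EffectResult
    interaction: EffectResult
    posthoc_p: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    correction: str


def compare_peths(
    peth_r: PETH,
    peth_u: PETH,
    alpha: float = 0.05,
    correction: str = "sidak",
) -> AnovaResult:
    """Rewarded-vs-unrewarded comparison across subjects.

    Both PETHs must hold one mean trace per subject, same subjects in
    the same order, same timepoints. The classical balanced two-way
    within-subjects ANOVA is computed from sums of squares: each effect
    is tested against its own subject-interaction error term
    (time: df (T−1, (T−1)(n−1)); trial type: (1, n−1); interaction:
    (T−1, (T−1)(n−1))). Post hoc per-timepoint paired t-tests with
    Šidák (default), Bonferroni or no correction give the significance
    mask.
    """
    if correction not in ("sidak", "bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    a = np.asarray(peth_r.trial_matrix, dtype=float)
    b = np.asarray(peth_u.trial_matrix, dtype=float)
    if a.shape != b.shape:
        raise ValueError("groups must have matching subjects × timepoints shapes")
    n, T = a.shape
    if n < 2 or T < 2:
        raise ValueError("need at least 2 subjects and 2 timepoints")

    y = np.stack([a, b])  # conditions (2) × subjects (n) × timepoints (T)
    c = 2
    gm = y.mean()
    m_c = y.mean(axis=(1, 2))
    m_s = y.mean(axis=(0, 2))
    m_t = y.mean(axis=(0, 1))
    m_cs = y.mean(axis=2)
    m_ct = y.mean(axis=1)
    m_st = y.mean(axis=0)

    ss_c = n * T * np.sum((m_c - gm) ** 2)
    ss_t = n * c * np.sum((m_t - gm) ** 2)
    ss_ct = n * np.sum((m_ct - m_c[:, None] - m_t[None, :] + gm) ** 2)
    ss_cs = T * np.sum((m_cs - m_c[:, None] - m_s[None, :] + gm) ** 2)
    ss_ts = c * np.sum((m_st - m_s[:, None] - m_t[None, :] + gm) ** 2)
    resid = (
        y
        - m_cs[:, :, None]
        - m_ct[:, None, :]
        - m_st[None, :, :]
        + m_c[:, None, None]
        + m_s[None, :, None]
        + m_t[None, None, :]
        - gm
    )
    ss_cts = np.sum(resid**2)

    def effect(ss, df1, ss_err, df2) -> EffectResult:
        ms = ss / df1
        ms_err = ss_err / df2
        F = float(ms / ms_err) if ms_err > 0 else float("inf") if ms > 0 else 0.0
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        return EffectResult(F=F, df1=df1, df2=df2, p=p)

    res_type = effect(ss_c, c - 1, ss_cs, (c - 1) * (n - 1))
    res_time = effect(ss_t, T - 1, ss_ts, (T - 1) * (n - 1))
    res_inter = effect(ss_ct, (c - 1) * (T - 1), ss_cts, (c - 1) * (T - 1) * (n - 1))

    # per-timepoint paired comparisons
    raw_p = np.empty(T)
    for t in range(T):
        diff = a[:, t] - b[:, t]
        if np.allclose(diff, diff[0]):
            raw_p[t] = 1.0 if diff[0] == 0 else 0.0
        else:
            raw_p[t] = stats.ttest_rel(a[:, t], b[:, t]).pvalue
    if correction == "sidak":
        adj = 1.0 - (1.0 - raw_p) ** T
    elif correction == "bonferroni":
        adj = np.minimum(raw_p * T, 1.0)
    else:
        adj = raw_p
    adj = np.where(np.isnan(adj), 1.0, adj)
    mask = adj < alpha
    return AnovaResult(
        time=res_time,
        trial_type=res_type,
        interaction=res_inter,
        posthoc_p=adj,
        sig_mask=mask,
        alpha=alpha,
        correction=correction,
    )
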