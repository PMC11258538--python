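# Methods

This note documents the models, defaults and numerical choices behind
lickcraft, and what the synthetic-data generator does and does not
emulate.

## The behavioral model

Mice lick in bouts: runs of rhythmic tongue protrusions whose
onset-to-onset interlick intervals (ILIs) cluster tightly, separated by
pauses. The generator treats bout onsets as a homogeneous Poisson
process on free time (default rate 0.08 bouts/s) with an enforced
minimum inter-bout gap equal to the analysis-side bout-break threshold
(0.5 s), so generated bout labels and bouts recovered by
`segment_bouts` at the same threshold agree exactly — a deliberate
coupling that turns bout segmentation into an exactly checkable round
trip. Within a bout, lick count follows a configurable discrete
distribution (default Poisson, mean 12, floored at 1) and ILIs are
truncated-normal with mean 0.146 s, SD 0.015 s and floor 0.05 s — a
simple unimodal choice matching the observed within-bout rhythm of mice
licking a recessed sipper. Lick durations are truncated-normal
(0.06 ± 0.02 s) inside [0.003, 0.2] s, the artifact filter's
keep-window, and clipped below the next interval so licks never
overlap; by construction the filter can never delete a clean true lick,
which is what makes "filtering leaves recall unchanged" a structural
property rather than a statistical one.

In the task, a reward (5 µl, metadata only) becomes available after an
intertrial interval drawn from an exponential with mean 18 s
conditioned on [2, 30] s, and is delivered at the first lick of the
first bout starting at or after availability; earlier bouts are
unrewarded and leave the availability clock untouched (reward-anchored
ITIs). Truncation is implemented by rejection — the conditional
distribution, not a clamp, which would pile mass at the bounds — so the
effective mean is the closed form a + 1/λ − Δe^(−λΔ)/(1 − e^(−λΔ)) ≈
12.51 s; the configured 18 s is the pre-truncation mean. Equal bounds
are accepted as a degenerate, deterministic interval.

## The sensor error model

Three error processes, each dialed by the validation recordings:

* false negatives per lick kind — short licks (tongue fails to reach
  the sipper) are missed with probability 10/27, sipper licks with
  4/203; a lick is short with probability 27/230;
* double detections — with probability 0.06 a surviving lick emits a
  second event at a gap drawn uniformly from (0.006, 0.045) s, always
  below the 0.05 s ILI criterion;
* snout artifacts — beam breaks outside any lick at 0.033 events/s with
  durations uniform on (0.08, 0.6) s, so most (about 77%) exceed the
  0.2 s duration ceiling and are filterable while a minority survive
  the filter, as residual false positives do in real recordings.

The double/snout rates are not reported anywhere as numbers; they were
fixed once so that the overall false-positive burden is ≈ 0.1 per
detected lick, the scale seen in validation sessions, and they are
ordinary config fields. Snout artifacts are placed by rejection with a
0.055 s guard margin around true events: a kept artifact can then never
sit within the ILI criterion's reach of a true lick, so the filter's
ILI rule (measured against the previous *kept* event) removes doubles
without ever cascading into true events. A removed double cannot shield
a following double for the same reason.

## Pose synthesis and video-lick segmentation

The pose generator renders each lick as a rectangular tongue-tip
displacement pulse on the 60 Hz frame grid (short licks peak between
the poke line and the sipper line, sipper licks beyond it), with
baseline noise and low tracking likelihood elsewhere. Two grid details
matter: every lick claims at least one frame, and consecutive licks are
separated by at least two inactive frames (boundary frames are trimmed
when licks crowd), because segmentation bridges single-frame gaps.
Under these rules `segment_video_licks` recovers lick count and kind
exactly and bounds to within one frame, and every sensor event onset
falls inside its video lick. Segmentation itself is operational — the
manual frame-by-frame annotation of a validation study is replaced by
likelihood and displacement thresholds surfaced in
`SegmentationConfig`.

What the generator does not emulate: tracking jitter on lick bounds,
partial protrusions hovering at threshold, camera dropout, or
correlated sensor/video clock drift (a constant-offset alignment is
provided instead). Passing tests therefore show the analysis logic is
correct under the stated error model, not that any particular hardware
achieves these error rates.

## Matching and metrics

An event belongs to the video lick whose closed [start, end] interval
contains its onset — one unambiguous rule for events straddling a
boundary. The first event per lick is its TP; later events in the same
lick and events in no lick are FP; unmatched licks are FN. Precision
and recall are reported pooled (ratio of summed counts) and as
mean ± SEM of per-session ratios; the two differ for unbalanced
sessions and validation studies that report "x ± y % over mice" use the
latter. Undefined ratios (empty denominators) are an explicit `None`,
never 0.

The "and/or" in the published filter rule is resolved as conjunctive
keep-criteria (duration window AND ILI guard) by default; the
disjunctive reading (remove only events failing both) is available via
`mode="disjunctive"`.

Fisher's exact test uses the "probability ≤ observed" two-sided
convention, computed in exact integer arithmetic: with margins fixed,
table probabilities share the denominator C(N, c1), so tables compare
by integer weights C(r1, a)·C(r2, c) and ties are exact rather than
float-fuzzy. An exhaustive enumeration oracle confirms equality (not
just closeness) on every table with N ≤ 40.

## Microstructure

ILIs are onset-to-onset (the lick-literature convention). The modal ILI
is the center of the maximal fixed-width histogram bin (10 ms bins,
right-closed, ceiling 0.5 s; ties break toward the smaller ILI) — a
binned mode is reproducible where a kernel-density mode depends on
bandwidth; the bin width is a config field since the original binning
is not documented. With the generator at 0.146/0.015 the mode lands in
the (0.14, 0.15] bin, center 0.145, so recovery is bin-limited at
±0.005. The primary ILI is the mean over the closed [0.05, 0.25] s
window. Pearson correlations use the product-moment formula with the
t-transform p-value; constant input returns a sentinel.

## Photometry

Both channels are detrended against sample index with Cleveland's
robust LOWESS as implemented in statsmodels (frac = 0.1, it = 3,
delta = 20). `delta` is interpreted in sample-index units (0.4 s at
50 Hz): exact local fits are computed at anchors at least 20 samples
apart and linearly interpolated between. The interpolation is an
acceleration with a real cost — between anchors the exact fit wobbles
at the local-fit noise scale (≈ σ/√(frac·n)), which linear
interpolation cannot track — so oracle comparisons against a
brute-force no-delta reference are made at delta = 0, where the two
algorithms coincide (observed agreement ~1e-13); the delta path is
validated separately against that bound on production-length traces.
Robustness scale is Cleveland's 6·median|r| bisquare.

ΔF is detrended-470 minus detrended-415 (the isosbestic channel shares
bleach and artifacts but no activity), then z-scored over the whole
session with the population SD; no trial-wise baseline z-scoring is
applied by default (per-trial baseline subtraction is available in
`PethConfig.baseline`). PETHs use nearest-sample alignment; the default
window −1.5 to +3.0 s at 50 Hz gives 226 timepoints, consistent with a
time factor of 225 numerator degrees of freedom in the group ANOVA.
Events without a full window are dropped and reported, never silently.

The rewarded-vs-unrewarded comparison is the classical balanced two-way
within-subject ANOVA computed from sums of squares, each effect tested
against its own subject-interaction error term (time: (T−1, (T−1)(n−1));
trial type: (1, n−1); interaction: as time). It matches a least-squares
repeated-measures reference to 1e-8 on small designs. The post hoc
family behind a shaded significance window is not standardized; the
default is per-timepoint paired t-tests with Šidák correction across
timepoints (Bonferroni and uncorrected available). With n = 22 subjects
and 226 timepoints the Šidák-corrected critical t (df 21) is ≈ 4.4, so
reliably flagged effects need to be ≳ 6 paired-difference SEMs tall;
power calculations in the tests use that figure.

The photometry simulator writes a two-exponential bleach (default
amplitudes 0.8/0.4, taus 300/1200 s over a baseline of 2), Gaussian
noise (SD 0.02), a positive double-exponential transient (peak 0.2,
rise 0.05 s, decay 0.4 s) at each rewarded first lick and a slower
negative dip (−0.1, rise 0.2 s, decay 0.8 s) at each unrewarded first
lick; the isosbestic channel carries the bleach scaled by 0.8 and
independent noise. Detrending attenuates event kernels slightly
(< 1% at these settings); end-to-end recovery tests therefore pin the
deterministic part by processing a noise-free replicate of the same
session through the identical chain and bound the stochastic part with
a 3σ CLT band.

## Problem sizes and degenerate inputs

Tests and the acceptance script use 30 min sessions where a statistic
needs the full session (microstructure, validation rates) and 10 min
sessions for the 100-replicate photometry loops and the 22-subject
group comparison — long enough that every session contains rewarded and
unrewarded bouts with overwhelming probability, short enough to keep
the full suite fast. Degenerate inputs are explicit throughout: empty
sessions yield empty summaries, undefined ratios and modes return
sentinels, constant ΔF raises, and parsers reject malformed rows by
number rather than dropping them.

## Known limitations

The generator's subjects are exchangeable draws of one parameter set;
between-animal variation (individual rhythms, learning across sessions)
must be modeled by varying `LickTrainParams` per subject, as the
examples do. The error model contains exactly the artifact classes the
post hoc filter targets plus a sub-ceiling snout fraction; real sensors
can produce false positives inside the keep-window with lick-like ILIs,
which no duration/ILI filter can remove. Photometry omits motion
artifacts and hemodynamics beyond the shared-bleach isosbestic model,
and the constant-offset clock alignment does not model drift.
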