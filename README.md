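# lickcraft

Analysis toolbox for consummatory-behavior experiments built around an
optical (infrared beam-break) lickometer, for researchers quantifying
licking microstructure in freely moving mice and relating it to neural
signals. It covers four jobs that usually live in ad hoc scripts:

1. **Sensor validation against video.** Tongue protrusions segmented from
   a 60 Hz pose-tracking table (DeepLabCut-style CSVs are read natively)
   are the ground truth; sensor events are matched to them by onset
   containment — first event in a protrusion is a true positive, extra
   events and events outside any protrusion are false positives, silent
   protrusions are false negatives — giving precision = TP/(TP+FP) and
   recall = TP/(TP+FN), a lick-kind ("short" vs "sipper") × missed/detected
   contingency with an exact two-sided Fisher test, and a post hoc artifact
   filter that keeps events with duration in [0.003, 0.2] s and interlick
   interval > 0.05 s (measured against the previous kept event).
2. **Lick microstructure.** Onset-to-onset interlick intervals (ILIs),
   greedy bout segmentation at a 0.5 s break, the modal ILI (peak of the
   10 ms-binned ILI distribution below 0.5 s), the primary ILI (mean ILI
   in 0.05–0.25 s) and session summaries with Pearson consistency
   statistics.
3. **Fiber photometry.** The standard two-channel dopamine-sensor chain:
   robust LOWESS detrending of the 470 nm signal and 415 nm isosbestic
   channels (frac 0.1, 3 robustifying iterations, 20-sample delta
   interpolation), ΔF = detrended signal − detrended isosbestic, session
   z-score, peri-event time histograms (−1.5 to +3 s, 226 points at 50 Hz)
   around rewarded and unrewarded first licks, and a two-way
   repeated-measures ANOVA (time × trial type) with per-timepoint
   Šidák-corrected paired tests giving a significance mask.
4. **Synthetic sessions with known truth.** A generator producing
   bout-structured lick trains (within-bout ILIs ≈ 0.146 ± 0.015 s),
   bout-triggered 5 µl rewards gated by an exponential intertrial interval
   (mean 18 s, truncated to [2, 30] s), sensor corruption (missed short
   licks at 10/27, missed sipper licks at 4/203, double-detections with
   gaps < 0.05 s, long snout artifacts), matching pose tracks and
   two-channel photometry traces — so every stage above is testable
   offline against generative truth.

## Worked example

```python
import numpy as np
import lickcraft as lc
from lickcraft.synthetic import PoseSimConfig

rng = np.random.default_rng(7)
truth = lc.simulate_task_session(lc.TaskConfig(session_duration=600.0),
                                 lc.LickTrainParams(), rng)
res = lc.corrupt_events(truth, lc.ErrorModel(), rng)
pose = lc.synthesize_pose(truth, PoseSimConfig(), rng)

licks = lc.segment_video_licks(pose, lc.SegmentationConfig())
pre = lc.detection_metrics(lc.match_events(licks, res.stream))
filtered, _ = lc.apply_posthoc_filter(res.stream, lc.FilterConfig())
post = lc.detection_metrics(lc.match_events(licks, filtered))
print(pre.precision, post.precision, pre.recall == post.recall)
```

prints

```
0.9323076923076923 0.9934426229508196 True
```

— the artifact filter removed double-detections (by the 0.05 s ILI
criterion) and long snout artifacts (by the 0.2 s duration ceiling),
raising precision from 93.2% to 99.3% while recall is untouched: the
filter's keep-window contains every clean true lick by construction.
The `examples/` directory has one narrative script per capability
(simulation, validation, microstructure, photometry); each prints the
numbers it computes and a line on what they mean. A thin CLI is included
(`lickcraft simulate|evaluate|microstructure|photometry|run`).

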