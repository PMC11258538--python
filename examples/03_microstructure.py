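"""Lick-microstructure summary of a filtered sensor stream.

Computes interlick intervals, bout segmentation at a 0.5 s break, the modal
ILI (peak of the 10 ms-binned distribution below 0.5 s) and the primary ILI
(mean in 0.05-0.25 s), then the across-session consistency correlation.
"""

import numpy as np

import lickcraft as lc

summaries = []
for seed in (0, 1):  # two consecutive "training sessions"
    rng = np.random.default_rng(seed)
    truth = lc.simulate_task_session(lc.TaskConfig(), lc.LickTrainParams(), rng)
    res = lc.corrupt_events(truth, lc.ErrorModel(), rng)
    filtered, _ = lc.apply_posthoc_filter(res.stream, lc.FilterConfig())
    summ = lc.summarize_session(filtered, reward_times=truth.reward_times)
    summaries.append(summ)
    print(f"session {seed}: {summ.n_licks} licks, {summ.n_bouts} bouts, "
          f"{summ.n_rewards} rewards, modal ILI {summ.modal_ili * 1000:.0f} ms, "
          f"primary ILI {summ.primary_ili * 1000:.1f} ms")

# across-mice consistency: each subject keeps its own rhythm across sessions,
# so the primary ILI of consecutive sessions correlates across subjects
subject_rng = np.random.default_rng(99)
x, y = [], []
for subject in range(8):
    ili_mean = subject_rng.normal(0.146, 0.008)  # individual within-bout rhythm
    vals = []
    for session in range(2):
        rng = np.random.default_rng(100 + 10 * subject + session)
        s = lc.generate_lick_train(
            lc.LickTrainParams(ili_mean=ili_mean), 1800.0, rng
        )
        vals.append(lc.primary_ili(s.within_bout_ilis(), lc.MicrostructureConfig()))
    x.append(vals[0])
    y.append(vals[1])
r, p = lc.pearson_r(np.array(x) * 1000, np.array(y) * 1000)
print(f"primary-ILI consistency across 8 subjects, session 0 vs 1: r={r:.2f} (p={p:.3f})")
print("Within-bout rhythm near 146 ms; the mode sits in the 0.14-0.15 s bin.")
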