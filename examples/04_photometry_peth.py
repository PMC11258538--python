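"""Fiber-photometry chain: detrend, isosbestic subtraction, z-score, PETHs.

Simulates dopamine-sensor traces for several subjects (positive transients
at rewarded first licks, dips at unrewarded first licks), processes each
session (LOWESS detrend of both channels, 470-415 subtraction, z-score),
extracts peri-event histograms and compares rewarded vs unrewarded with a
two-way repeated-measures ANOVA plus a per-timepoint significance mask.
"""

import numpy as np

import lickcraft as lc
from lickcraft.synthetic import PhotoSimConfig

n_subjects = 8
subj_r, subj_u = [], []
for seed in range(n_subjects):
    rng = np.random.default_rng(seed)
    truth = lc.simulate_task_session(
        lc.TaskConfig(session_duration=600.0), lc.LickTrainParams(), rng
    )
    trace = lc.simulate_photometry(truth, PhotoSimConfig(), rng)
    z = lc.preprocess(trace)  # lowess frac=0.1 it=3 delta=20, dF, z-score
    pr, _ = lc.compute_peth(z, truth.reward_times, trace.rate)
    pu, _ = lc.compute_peth(z, truth.unrewarded_first_lick_times(), trace.rate)
    subj_r.append(pr)
    subj_u.append(pu)

peth_r = lc.subject_peth_matrix(subj_r, group="rewarded")
peth_u = lc.subject_peth_matrix(subj_u, group="unrewarded")
res = lc.compare_peths(peth_r, peth_u)

print(f"subjects: {n_subjects}; PETH window {peth_r.rel_time[0]:+.1f}..",
      f"{peth_r.rel_time[-1]:+.1f} s, {peth_r.rel_time.size} timepoints")
print(f"rewarded peak z = {peth_r.mean.max():.2f}; "
      f"unrewarded trough z = {peth_u.mean.min():.2f}")
for name, eff in (("time", res.time), ("trial type", res.trial_type),
                  ("interaction", res.interaction)):
    print(f"{name:12s} F({eff.df1},{eff.df2}) = {eff.F:.2f}, p = {eff.p:.3g}")
sig = res.sig_mask
print(f"significant timepoints (Sidak-corrected paired tests): {sig.sum()}/{sig.size},"
      f" spanning {peth_r.rel_time[sig].min():+.2f}..{peth_r.rel_time[sig].max():+.2f} s")
print("The positive rewarded transient and the unrewarded dip separate the")
print("two trial types, mirroring phasic dopamine at reward delivery.")
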