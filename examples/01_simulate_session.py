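"""Simulate a 30 min bout-triggered licking session with a corrupted sensor stream.

Builds a ground-truth lick train (bouts of ~0.146 s rhythm), schedules 5 µl
rewards on the first lick of a bout behind a truncated-exponential ITI, and
applies the lickometer's error model (missed short licks, double detections,
snout artifacts). Prints the session's composition.
"""

import numpy as np

import lickcraft as lc

rng = np.random.default_rng(42)
truth = lc.simulate_task_session(lc.TaskConfig(), lc.LickTrainParams(), rng)
res = lc.corrupt_events(truth, lc.ErrorModel(), rng)

print(f"ground truth : {truth.n_licks} licks in {len(truth.bouts)} bouts, "
      f"{truth.n_rewards} rewards over {truth.duration:.0f} s")
print(f"sensor stream: {len(res.stream)} events "
      f"({res.labels.count('true')} true, {res.labels.count('double_fp')} doubles, "
      f"{res.labels.count('snout_fp')} snout artifacts); "
      f"{sum(res.dropped)} licks missed")
print("A missed lick is a sensor false negative; doubles and snout artifacts")
print("are the two false-positive classes the post hoc filter targets.")
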