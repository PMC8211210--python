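"""Generate a reference-back-2 session and inspect its structure.

Builds the default 12-block x 90-trial session, replays the task rule to
label memory state, correct responses and the three gate switches, samples
DDM behavior, and applies the standard trial exclusions.
"""

import numpy as np

from gatepipe import (
    RegressionSpec,
    TaskConfig,
    apply_exclusions,
    generate_session,
    label_trials,
    simulate_behavior,
)

seq = label_trials(generate_session(TaskConfig(), seed=7))
seq = simulate_behavior(seq, RegressionSpec(), seed=8)
seq = apply_exclusions(seq)
t = seq.table

print(f"trials: {len(t)}  (12 blocks x 90)")
print(f"updating trials: {(t.wm_state == 'updating').mean():.3f} of session")
for col in ("input_switch", "output_switch", "response_switch"):
    print(f"{col:16s} rate: {t[col].dropna().astype(bool).mean():.3f}")
corr = t[["input_switch", "output_switch", "response_switch"]].dropna().astype(float).corr()
print(f"max |pairwise switch correlation|: "
      f"{np.abs(corr.to_numpy()[~np.eye(3, dtype=bool)]).max():.3f}")
print(f"excluded trials: {t.excluded.sum()} "
      f"({t.loc[t.excluded, 'exclude_reason'].value_counts().to_dict()})")
print(f"accuracy on retained trials: {seq.retained().accuracy.mean():.3f}")
print(f"mean RT on retained correct trials: "
      f"{seq.retained().query('accuracy').rt.mean():.3f} s")
# The switch rates hover near 0.5 and are mutually uncorrelated, which is
# what lets the condition regression separate the three gating levels.
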