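"""Hierarchical DDM fit of a planted gate-switch threshold effect.

Simulates 8 subjects whose decision threshold rises by +0.3 on response
switches, fits the hierarchical condition-regression model by MCMC, and
reports the group-level coefficients with 95% highest-density intervals,
convergence diagnostics and a posterior-predictive check.
"""

import numpy as np

from gatepipe import (
    REFERENCE_CELL,
    RegressionSpec,
    SamplerSettings,
    TaskConfig,
    apply_exclusions,
    fit_hierarchical,
    posterior_predictive,
    simulate_behavior,
)
from gatepipe.fitting import dic
from gatepipe.task import TrialSequence

import pandas as pd


def two_cell_subject(seed, n_per_cell=150):
    rng = np.random.default_rng(seed)
    rows = []
    for cell_switch in (False, True):
        for k in range(n_per_cell):
            rows.append(dict(
                block=0, trial_in_block=k + 2, stimulus="X", category="letter",
                frame_color="blue", wm_state="maintenance",
                update_frequency_phase="rare", exclude_flag=False,
                correct_response=rng.choice(["same", "different"]),
                input_switch=False, output_switch=False,
                response_switch=cell_switch,
                undefined_reference=False, undefined_switch=False))
    t = pd.DataFrame(rows)
    for c in ("input_switch", "output_switch", "response_switch"):
        t[c] = t[c].astype("boolean")
    seq = TrialSequence(t, TaskConfig())
    spec = RegressionSpec(a_mr=1.5, v_mr=2.0, t=0.3,
                          a_cell={"mnt.iR.oR.rS": 0.3})
    return apply_exclusions(simulate_behavior(seq, spec, seed=seed + 1))


trials = {s: two_cell_subject(100 + 7 * s) for s in range(8)}
settings = SamplerSettings(chains=2, draws=700, burn_in=300, thin=2)
samples, result = fit_hierarchical(trials, settings, seed=42)

print(result.coefficients.to_string(index=False,
                                    float_format=lambda x: f"{x: .3f}"))
print(f"\nmax R-hat: {result.max_rhat:.3f}  (converged: {result.converged})")
print(f"DIC: {dic(samples, trials, stride=5):.1f}")
ppc = posterior_predictive(samples, trials, seed=1)
print(f"posterior predictive: {ppc.n_sim} simulated datasets; observed "
      f"signed-RT quantiles inside the envelope at {100 * ppc.coverage():.0f}% "
      f"of points")
# The a_identity row is the threshold increment on the natural scale: its
# interval should cover the planted +0.3 and exclude 0, while drift shows
# no effect (none was planted).
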