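"""Score the executive-function battery and fit the dissociation GLMs.

Simulates stop-signal trials, estimates the stop-signal reaction time by
the integration method, then fits the two behavioral models on a planted
cohort: novelty regressed on associative ability and the executive RT
composite, and the same for appropriateness.
"""

import logging

import numpy as np

logging.getLogger("flowcpm").setLevel(logging.ERROR)  # silence per-SSD notes

from flowcpm import dissociation_glm, ssrt_integration
from flowcpm.synthetic import CohortSpec, ef_trials_to_ssrt_inputs, make_cohort, make_ef_trials

# --- stop-signal scoring ------------------------------------------------
trials = make_ef_trials(5, true_ssrt=250.0, go_rt_mean=500.0, go_rt_sd=80.0, seed=0)
estimates = []
for pid in trials["participant_id"].unique():
    go, by_ssd = ef_trials_to_ssrt_inputs(trials, pid)
    estimates.append(ssrt_integration(go, by_ssd))
print(f"integration-method SSRT, 5 simulated participants "
      f"(true latency 250 ms): {np.round(estimates, 0)}")

# --- dissociation GLMs --------------------------------------------------
table = make_cohort(CohortSpec(n_participants=1500, seed=1))
for outcome in ("novelty", "appropriateness"):
    res = dissociation_glm(table, outcome, model="1")
    print(f"\n{outcome} ~ associative ability + EF composites (n={res.n}):")
    for term in ("assoc_z", "ef_rt_z"):
        row = res[term]
        print(f"  {term:8s} beta={row['beta']:+.3f}  se={row['se']:.3f}  "
              f"t={row['t']:+.2f}  p_bonf={row['p_bonferroni']:.2g}")
print("\nThe planted pattern dissociates the outcomes: novelty loads on "
      "association, appropriateness on executive speed (negative RT beta "
      "= faster responders are rated more appropriate).")
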