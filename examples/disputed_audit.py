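"""Disputed-case audit: who makes the grave errors?

Simulates a hospital-scale cohort (8,250 cases) where manual ratings
carry rare gross errors, flags the disputed cases (automated and manual
ratings more than 1.8 y apart), re-rates them with a blinded 3-rater
panel and counts, per method, the grave errors (more than 1.5 y from
the panel mean).
"""

import numpy as np

from bonegate import SimulationSpec, disputed_case_analysis, simulate_cohort

spec = SimulationSpec(
    n_cases=8250, sigma_auto=0.33, sigma_rater=0.52, n_raters=4, seed=4,
)
cases = simulate_cohort(spec, with_bones=False)
auto = np.array([c.auto_ba for c in cases])
ratings = np.array([c.manual_ratings for c in cases])

audit = disputed_case_analysis(auto, ratings[:, 0], ratings[:, 1:4])
print(f"cohort size:            {audit.n_total}")
print(f"disputed (>1.8 y apart): {audit.n_disputed} "
      f"({audit.disputed_rate_percent}%)")
print(f"automated closer to ref: {audit.n_auto_closer} of {audit.n_disputed}")
print(f"grave manual errors (>1.5 y): {audit.n_manual_grave}")
print(f"grave automated errors (>1.5 y): {audit.n_auto_grave}")
if audit.n_auto_grave:
    print(f"fold difference:         {audit.grave_fold}x")

print("\nMost disputes trace back to manual gross errors: the method with the")
print("smaller error SD is almost always the one closer to the blinded panel.")
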