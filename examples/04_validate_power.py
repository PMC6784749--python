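"""Monte-Carlo check that a computed sample size delivers its nominal power.

Computes the CDI 30% cluster requirement, then simulates 2000 trials at the
per-arm formula size (gamma-distributed cluster rates, Poisson counts,
cluster-summary t test) and reports the empirical rejection rate, plus the
type-I error rate under the null.
"""

import math

from crtplan import clusters_required, load_paper_fixture, simulate_trial_power

spec = load_paper_fixture("cdi").design_spec(effect_size=0.30)
per_arm = math.ceil(clusters_required(spec).clusters_unrounded)
print(f"per-arm formula size: {per_arm} clusters")

res = simulate_trial_power(spec, per_arm, n_sims=2000, seed=20)
print(f"empirical power: {res.empirical_power:.3f} (nominal 0.80)")

null = simulate_trial_power(spec, per_arm, n_sims=2000, seed=21, under_null=True)
print(f"type-I error under the null: {null.empirical_power:.3f} (nominal 0.05)")

# Empirical power near (typically slightly above) 0.80 confirms the closed
# form is adequately calibrated for this design; the null rejection rate
# should sit within Monte-Carlo noise of alpha.
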