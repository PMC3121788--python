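"""Monte-Carlo digestion of a synthetic loop ensemble vs the analytic model.

Builds a 200-loop nucleoid (42 kbp mean, 2% embedded), simulates limited
DNase-I digestion, and checks the sampled time course against the exact
per-loop expectation.
"""

import numpy as np

from nmloops import (
    AccessibilityProfile,
    SimulationConfig,
    analytic_attached_fraction,
    build_nucleoid_ensemble,
    simulate_digestion,
)

profile = AccessibilityProfile(k0=2e-4, alpha=2.0)
model = build_nucleoid_ensemble(
    n_loops=200, mean_kbp=42.0, cv=0.1, embedded_target=0.02, profile=profile, seed=11
)
print(f"ensemble: {model.n_loops} loops, total {model.total_bp/1e6:.2f} Mbp, "
      f"embedded fraction {model.embedded_fraction:.3f}")

config = SimulationConfig(n_nucleoids=300, seed=12)
result = simulate_digestion(model, config, label="demo")

print("\n  t(min)   MC %attached   analytic   3*SE")
for p in result.timecourse.points:
    ana = 100 * np.average(
        [analytic_attached_fraction(lp, profile, p.time_min) for lp in model.loops],
        weights=[lp.total_bp for lp in model.loops],
    )
    se = p.sd / np.sqrt(p.n)
    print(f"  {p.time_min:6.0f}   {p.pct_attached:10.2f}   {ana:8.2f}   {3*se:5.2f}")
print("\nThe sampled percentages track the analytic expectation within")
print("Monte-Carlo error and never fall below the 2% embedded floor:")
print("distal loop DNA is lost first, MAR-buried DNA never.")
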