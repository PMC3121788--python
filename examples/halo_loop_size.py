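"""DNA-halo loop-size estimation and group statistics.

Simulates noisy halo measurements for two synthetic age groups with
different mean loop sizes, estimates the loop sizes back from the halo
radii, tests the group difference, and checks NM resilience.
"""

from nmloops import (
    AccessibilityProfile,
    build_nucleoid_ensemble,
    loop_size_estimate,
    nm_resilience,
    reference_loop_sizes,
    simulate_halo_radii,
    students_t_test,
    summarize_measurements,
)

profile = AccessibilityProfile(k0=2e-4, alpha=2.0)
groups = {}
for label, mean_kbp, seed in (("young", 36.0, 21), ("old", 42.0, 22)):
    model = build_nucleoid_ensemble(100, mean_kbp, 0.0, 0.0, profile, seed=seed)
    groups[label] = simulate_halo_radii(model, n=50, noise_cv=0.08, seed=seed, label=label)

for label, ms in groups.items():
    est = loop_size_estimate(ms)
    print(f"{label:>6}: halo radius {ms.records['halo_radius_um'].mean():.2f} um "
          f"-> loop size {est.mean_kbp:.1f} +/- {est.sd_kbp:.1f} kbp (n={est.n})")
print("A 42 kbp loop unwinds into a 7.14 um halo (out-and-back B-DNA at 0.34 nm/bp).\n")

res = students_t_test(
    groups["young"].column("halo_radius_um"),
    groups["old"].column("halo_radius_um"),
    alpha=0.01,
)
print(f"Student's t (pooled): t={res.t_statistic:.2f}, df={res.degrees_of_freedom:.0f}, "
      f"p={res.p_value:.2e}, significant at 99%: {res.significant}")

resil = nm_resilience(groups["old"])
print(f"NM/nucleus diameter ratio {resil['ratio']:.2f} -> resilient NM: {resil['resilient']}")
print("(The matrix measuring wider than its nucleus indicates a rigid,")
print(" self-supporting proteinaceous framework.)\n")

print("Bundled reference loop sizes (halo-derived, kbp):")
print(reference_loop_sizes().to_string(index=False))
print("\nPer-field summary of the simulated 'old' group:")
print(summarize_measurements(groups["old"]).to_string(index=False))
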