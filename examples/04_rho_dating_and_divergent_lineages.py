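"""Rho coalescence dating and the persistent-ancestor shortening effect.

Simulates the persistent-ancestor genealogy (an ancestral lineage 10,000
years old; 30% of modern tips are exact unmutated copies of it; the rest
branched off throughout its lifetime), then dates the clade with rho using
all tips vs the most divergent tips.
"""

from mitotempo import (
    ClockCalibration,
    HaplogroupSample,
    SimulationConfig,
    age,
    rho,
    simulate_genealogy_mode,
)

T = 10_000.0
config = SimulationConfig(
    sampling=((-50.0, 200), (T, 1)),
    persistent_fraction=0.3,
    branch_time_mode="uniform",
    seed=5,
)
profiles, truth = simulate_genealogy_mode(config)
clock = ClockCalibration("truth", 1.0 / (config.mu_site * config.L))
sample = HaplogroupSample("R", frozenset(), profiles[1:])

print(f"true root age: {T:,.0f} yr; {sum(t['persistent'] for t in truth['per_tip'])} of "
      f"{len(truth['per_tip'])} tips are unmutated ancestral copies")
for mode in ("all", "upper_quartile", "max"):
    est = rho(sample, mode)
    a = age(est, clock)
    print(f"mode={mode:<15} rho={est.rho:5.2f} (n={est.n:3d})  "
          f"age = {a.years:7,.0f} yr  [{a.ci_low:,.0f}, {a.ci_high:,.0f}]")
print("\nPlain rho is dragged down by persistent unmutated lineages and by tips")
print("that branched off recently; restricting the mean to the most divergent")
print("tips removes a large part of that shortening bias, though at this low")
print("mutation supply (mu*L*T ~ 2.7) even the maximum stays below the truth.")
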