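"""Time dependency emerging from demography alone, on simulated mitogenomes.

Simulates serially sampled mitogenomes under a female effective size that
grew exponentially toward the present, runs the full pipeline (periods,
pairing, theta per period, regression), and shows the recent-period rate
exceeding the old-period rate even though every branch mutated at the same
per-year rate.
"""

from mitotempo import SimulationConfig, analyze_profiles, simulate_coalescent_mode

config = SimulationConfig(
    sampling=((-50.0, 60), (1_000.0, 15), (5_000.0, 15), (15_000.0, 15), (30_000.0, 15)),
    seed=11,
)
profiles, truth = simulate_coalescent_mode(config)
print(f"simulated {len(profiles)} tip-dated mitogenomes "
      f"(true TMRCA {truth['tmrca_years_bp']:,.0f} yr BP, mu = {config.mu_site:.1e}/site/yr)")

result = analyze_profiles(profiles, edges=[0, 2_500, 10_000, 20_000, 60_000])
print(result["rates"][["period", "mean_age_bp", "n_pairs", "sum_d", "theta_site"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))
reg = result["regression"]
print(f"\nregression of theta_site on period age: slope = {reg['slope']:.3g} "
      f"(r = {reg['r']:.2f}, p = {reg['p']:.3g})")
print("The apparent per-site rate is inflated at shallow time depths because")
print("modern/ancient pairs share polymorphism much older than the period; the")
print("negative slope is the time-dependency signature (with only four periods")
print("the slope's p-value is weak, but the monotone decay is unmistakable).")
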