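"""Response times vs stimulus dissimilarity, and Stroop congruency checks.

Fits the two-stage RT model (per-participant OLS, then across-participant
tests): RT should fall linearly as the current stimulus becomes more
dissimilar from the previous one, with a condition offset but no interaction.
Also runs the congruent-vs-incongruent Stroop performance contrasts.
"""

import serialbias as sb

config = sb.SimulationConfig(n_participants=20, seed=5,
                             include_trajectories=False)
trials, _, _ = sb.simulate_experiment(config)

fit = sb.rt_dissimilarity_model(trials)
s = fit.slope
print(f"RT slope: {s.mean:.3f} ms per degree of dissimilarity "
      f"[{s.ci_low:.3f}, {s.ci_high:.3f}]  (injected {config.rt_slope_per_degree})")
o = fit.condition_offset
print(f"condition offset (Stroop rel. NoStroop): {o.mean:+.1f} ms "
      f"[{o.ci_low:+.1f}, {o.ci_high:+.1f}]  (injected -{config.rt_condition_offset})")
i = fit.interaction
print(f"interaction: {i.mean:+.3f} ms/deg, p = {i.p:.3f} "
      "(injected 0: should not be significant)")

print("\nStroop task performance, congruent vs incongruent:")
for cond, res in sb.stroop_congruency_contrast(trials).items():
    rt, acc = res["rt"], res["accuracy"]
    print(f"  {cond}: RT {rt.mean_a:.3f} vs {rt.mean_b:.3f} s "
          f"(t({rt.df}) = {rt.t:.2f}, p = {rt.p:.2g}); "
          f"accuracy {acc.mean_a:.1f} vs {acc.mean_b:.1f}% (p = {acc.p:.2g})")
print("(the fixed-key condition should show no congruency effect)")
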