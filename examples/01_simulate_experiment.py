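"""Simulate a direction-report experiment and inspect its ground truth.

Generates a small dual-task experiment (direction estimation with and without
a concurrent Stroop task), prints the tables it produces and the injected
per-subject serial-bias amplitudes that downstream stages should recover.
"""

import serialbias as sb

config = sb.SimulationConfig(n_participants=6, n_trials_per_condition=192,
                             block_size=96, seed=1)
trials, trajectories, truth = sb.simulate_experiment(config)

print(f"trials: {len(trials)} rows "
      f"({config.n_participants} participants x 2 conditions x "
      f"{config.n_trials_per_condition} trials)")
print(trials[["participant", "condition", "trial_index", "target", "report",
              "report_rt", "stroop_word", "stroop_color"]].head())

print(f"\ntrajectories: {len(trajectories)} cursor samples at "
      f"{config.trajectory_sample_rate:.0f} Hz")
print(trajectories.head())

print("\ninjected per-subject bias amplitudes (asymmetry %-points; positive ="
      "\nattracted toward the previous trial's direction, negative = repelled):")
print(truth.subjects.pivot(index="participant", columns="condition",
                           values="bias_amplitude_pct").round(2))
print(f"\nconversion used internally: {truth.percent_per_degree:.3f} "
      "asymmetry %-points per degree of DoG amplitude")
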