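import pytest
from hypothesis import HealthCheck, settings

import serialbias as sb

settings.register_profile(
    "det", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_sim():
    """Small but structured experiment: 8 participants x 2 x 192 trials with
    trajectories at 40 Hz."""
    cfg = sb.SimulationConfig(n_participants=8, n_trials_per_condition=192,
                              block_size=96, trajectory_sample_rate=40.0,
                              seed=7)
    trials, traj, gt = sb.simulate_experiment(cfg)
    return cfg, trials, traj, gt


@pytest.fixture(scope="session")
def small_corrected(small_sim):
    cfg, trials, traj, gt = small_sim
    corrected, models = sb.correct_trials(trials)
    paired = sb.add_previous_context(corrected)
    return cfg, paired, traj, gt, models

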