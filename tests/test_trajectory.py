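import numpy as np
import pandas as pd
import pytest

import serialbias as sb
from serialbias.trajectory import (_participant_surface, first_frame_sign_analysis,
                                   first_last_sign_model, frame_bias,
                                   second_frame_repulsive_fraction,
                                   trajectory_bias_surface)


def test_participant_surface_degenerates_to_cell_means():
    """With vanishing kernel SDs the surface reproduces raw cell means."""
    time_grid = np.array([-0.2, -0.1, 0.0])
    diss_grid = np.array([10.0, 50.0])
    ttr, diss, dev = [], [], []
    expected = np.zeros((3, 2))
    rng = np.random.default_rng(0)
    for i, t in enumerate(time_grid):
        for j, d in enumerate(diss_grid):
            vals = rng.normal(0, 3, 5)
            expected[i, j] = vals.mean()
            ttr += [t] * 5
            diss += [d] * 5
            dev += vals.tolist()
    surf = _participant_surface(np.array(ttr), np.array(diss), np.array(dev),
                                time_grid, diss_grid, 1e-4, 1e-3)
    assert np.allclose(surf, expected, atol=1e-8)


def test_participant_surface_masks_empty_cells():
    time_grid = np.array([-0.1, 0.0])
    diss_grid = np.array([10.0, 170.0])
    # samples only at (t=0, d=10)
    surf = _participant_surface(np.zeros(4), np.full(4, 10.0), np.ones(4),
                                time_grid, diss_grid, 0.01, 5.0)
    assert np.isfinite(surf[1, 0])
    assert np.isnan(surf[0, 1]) and np.isnan(surf[1, 1])


def test_surface_group_level_structure(small_corrected):
    _, paired, traj, _, _ = small_corrected
    surfaces = trajectory_bias_surface(traj, paired, min_trials=20)
    assert set(surfaces) == {"Stroop", "NoStroop"}
    for s in surfaces.values():
        assert s.bias.shape == (90, 90)
        assert s.time_grid[0] < 0 and s.time_grid[-1] == 0.0
        assert s.support_ms > 0
        # early repulsive lobe dominates mid-dissimilarity early cells
        early = s.time_grid < -0.6
        mid = (s.diss_grid > 50) & (s.diss_grid < 120)
        cells = s.bias[np.ix_(early, mid)]
        assert np.nanmean(cells) < 0
        # masked cells never enter the group mean
        assert not np.isinf(np.nan_to_num(s.bias)).any()


def test_surface_invariant_to_participant_relabeling(small_corrected):
    _, paired, traj, _, _ = small_corrected
    base = trajectory_bias_surface(traj, paired, min_trials=20)
    ids = sorted(paired["participant"].unique())
    mapping = {p: q for p, q in zip(ids, np.roll(ids, 3))}
    paired2 = paired.assign(participant=paired["participant"].map(mapping))
    traj2 = traj.assign(participant=traj["participant"].map(mapping))
    perm = trajectory_bias_surface(traj2, paired2, min_trials=20)
    for cond in base:
        assert np.allclose(base[cond].bias, perm[cond].bias, equal_nan=True)
        assert np.allclose(base[cond].t, perm[cond].t, equal_nan=True)


def test_surface_min_trials_too_large_errors(small_corrected):
    _, paired, traj, _, _ = small_corrected
    with pytest.raises(ValueError, match="min_trials"):
        trajectory_bias_surface(traj, paired, min_trials=10_000)


def test_surface_percent_unit_bounded(small_corrected):
    _, paired, traj, _, _ = small_corrected
    surfaces = trajectory_bias_surface(traj, paired, min_trials=20,
                                       unit="percent")
    for s in surfaces.values():
        vals = s.bias[np.isfinite(s.bias)]
        assert vals.min() >= -100.0 and vals.max() <= 100.0


def test_first_frame_sign_tracks_agreement_knob(small_corrected):
    """Coupling first/last signs with probability p makes the conditional
    mean first-frame sign ~ 2p - 1 in each final-sign stratum."""
    cfg, paired, traj, _, _ = small_corrected
    frames = frame_bias(traj, paired)
    res = first_frame_sign_analysis(frames)
    expected = 2 * cfg.first_frame_agreement - 1  # 0.22
    for (cond, final_sign), t in res["strata"].items():
        assert t is not None
        assert t.mean == pytest.approx(final_sign * expected, abs=0.12)


def test_first_frame_independence_is_null():
    cfg = sb.SimulationConfig(n_participants=6, n_trials_per_condition=96,
                              block_size=96, trajectory_sample_rate=30.0,
                              first_frame_agreement=0.5, seed=21)
    trials, traj, _ = sb.simulate_experiment(cfg)
    corrected, _ = sb.correct_trials(trials)
    paired = sb.add_previous_context(corrected)
    frames = frame_bias(traj, paired)
    res = first_frame_sign_analysis(frames)
    for t in res["strata"].values():
        assert t is None or abs(t.mean) < 0.2
    model = first_last_sign_model(frames)
    assert model["test"].p > 0.01


def test_first_last_sign_model_detects_coupling(small_corrected):
    _, paired, traj, _, _ = small_corrected
    frames = frame_bias(traj, paired)
    model = first_last_sign_model(frames)
    assert model["test"].mean > 0
    assert model["test"].p < 0.05


def test_first_last_sign_model_degenerate_participant_falls_back():
    rng = np.random.default_rng(4)
    rows = []
    for p in (1, 2, 3):
        for i in range(40):
            first = 1.0 if p == 1 else float(rng.choice([-1, 1]))
            last = float(rng.choice([-1, 1]))
            rows.append({"participant": p, "condition": "Stroop",
                         "trial_index": i, "n_samples": 5,
                         "first_sign": first, "second_sign": -first,
                         "last_sign": last, "first_dev": first,
                         "last_dev": last})
    model = first_last_sign_model(pd.DataFrame(rows))
    assert model["n_capped"] >= 1
    assert len(model["slopes"]) == 3  # run completes, everyone contributes


def test_second_frame_repulsive_fraction_tracks_knob(small_corrected):
    cfg, paired, traj, _, _ = small_corrected
    frames = frame_bias(traj, paired)
    res = second_frame_repulsive_fraction(frames)
    expected = 100.0 * cfg.second_frame_repulsive_rate
    half = 3.0 * np.sqrt(expected * (100 - expected) / res["n"])
    assert abs(res["percent_repulsive"] - expected) < max(half, 3.0)


def test_second_frame_all_monotone_attractive_is_zero():
    frames = pd.DataFrame({
        "participant": [1] * 10, "condition": ["Stroop"] * 10,
        "trial_index": range(10), "n_samples": 5,
        "first_sign": 1.0, "second_sign": 1.0, "last_sign": 1.0,
        "first_dev": 1.0, "last_dev": 1.0,
    })
    assert second_frame_repulsive_fraction(frames)["percent_repulsive"] == 0.0
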