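import numpy as np
import pytest

import serialbias as sb
from serialbias import anisotropy as an
from serialbias.circular import toward_previous_sign, wrap_signed
from serialbias.simulate import SimulationConfig, cardinal_bias_profile


def _sin4(theta, amp=5.0):
    return amp * np.sin(np.deg2rad(4.0 * theta))


def test_zero_errors_give_zero_model():
    rng = np.random.default_rng(0)
    theta = rng.uniform(0, 360, 2000)
    model = an.fit_anisotropy(theta, np.zeros_like(theta), an.cardinal_scheme())
    pred = model.predict_mean(np.linspace(0, 359, 720))
    assert np.max(np.abs(pred)) < 1e-8
    for poly in model.polynomials:
        assert np.max(np.abs(poly.convert().coef)) < 1e-8


def test_recovers_injected_sin4_profile():
    rng = np.random.default_rng(1)
    theta = rng.uniform(0, 360, 10000)
    err = _sin4(theta) + rng.normal(0, 2, len(theta))
    model = an.select_scheme(theta, err)
    grid = np.linspace(0, 359.5, 720)
    rms = np.sqrt(np.mean((model.predict_mean(grid) - _sin4(grid)) ** 2))
    assert rms < 0.5


def test_empty_bin_error_names_the_bin():
    rng = np.random.default_rng(2)
    theta = rng.uniform(50, 310, 500)  # nothing within 45 deg of 0/360
    with pytest.raises(an.AnisotropyError, match="0 deg"):
        an.fit_anisotropy(theta, np.zeros_like(theta), an.cardinal_scheme())


def test_min_per_bin_floor_enforced():
    rng = np.random.default_rng(3)
    theta = rng.uniform(0, 360, 60)  # ~15 per bin < 25
    with pytest.raises(an.AnisotropyError, match="min_per_bin"):
        an.fit_anisotropy(theta, np.zeros_like(theta), an.cardinal_scheme())


@pytest.mark.parametrize("sign, expected_scheme", [
    ("repel", "oblique"),    # discontinuity at cardinals -> oblique bins
    ("attract", "cardinal"),  # smooth at cardinals -> cardinal bins
])
def test_scheme_selection_matches_bias_physics(sign, expected_scheme):
    cfg = SimulationConfig(cardinal_bias_sign=sign, cardinal_bias_shape="local")
    rng = np.random.default_rng(4)
    theta = rng.uniform(0, 360, 10000)
    err = cardinal_bias_profile(theta, cfg) + rng.normal(0, 2, len(theta))
    assert an.select_scheme(theta, err).scheme.name == expected_scheme


def test_tie_breaks_to_cardinal_scheme():
    rng = np.random.default_rng(5)
    theta = rng.uniform(0, 360, 2000)
    err = rng.normal(0, 2, len(theta))
    card = an.fit_anisotropy(theta, err, an.cardinal_scheme())
    obli = an.fit_anisotropy(theta, err, an.oblique_scheme())
    obli.log_likelihood = card.log_likelihood  # force an exact tie
    assert an._choose(card, obli) is card


def test_apply_correction_flags_and_preserves_counts():
    rng = np.random.default_rng(6)
    theta = rng.uniform(0, 360, 4000)
    err = rng.normal(0, 5, len(theta))
    model = an.fit_anisotropy(theta, err, an.cardinal_scheme())
    res = an.apply_correction(model, theta, err)
    assert len(res) == len(theta)  # never drops trials
    # outlier rule: |corrected| > 3 x local SD
    manual = np.abs(res["corrected_error"]) > 3.0 * res["local_sd"]
    assert (res["outlier"] == manual).all()
    # a 40-deg corrected error at ~5-deg local SD must be flagged
    res2 = an.apply_correction(model, np.array([10.0]), np.array([40.0]))
    assert bool(res2["outlier"].iloc[0])
    # a small error is corrected but not flagged
    res3 = an.apply_correction(model, np.array([10.0]), np.array([2.0]))
    assert not bool(res3["outlier"].iloc[0])
    assert abs(res3["corrected_error"].iloc[0] - 2.0) < 1.5


def test_correction_is_idempotent():
    """Correcting already-corrected errors changes them by < 0.1 deg RMS:
    once the anisotropy is removed, a second pass finds only fit noise."""
    rng = np.random.default_rng(7)
    theta = rng.uniform(0, 360, 20000)
    err = rng.normal(0, 2, len(theta))
    m1 = an.select_scheme(theta, err)
    c1 = an.apply_correction(m1, theta, err)["corrected_error"].to_numpy()
    m2 = an.select_scheme(theta, c1)
    c2 = an.apply_correction(m2, theta, c1)["corrected_error"].to_numpy()
    assert np.sqrt(np.mean((c2 - c1) ** 2)) < 0.1


def test_correct_trials_outlier_fraction(small_corrected):
    cfg, paired, _, _, models = small_corrected
    # default world has ~0.5% injected uniform outliers; the flag rate must
    # stay below 2%
    assert paired["error_outlier"].mean() < 0.02
    assert len(models) == cfg.n_participants
    assert paired["corrected_error"].notna().all()


def test_correct_trials_removes_cardinal_bias():
    """Per-participant correction flattens a 5-deg sin(4*theta) anisotropy:
    direction-binned means of corrected errors stay below max(0.5, 0.1*a).
    Uses a low-noise, high-trial world where the bound is statistically
    meaningful."""
    cfg = sb.SimulationConfig(
        n_participants=2, n_trials_per_condition=4800, block_size=96,
        bias_amplitude_mean_by_condition={"Stroop": 0.0, "NoStroop": 0.0},
        bias_amplitude_sd=0.0, cardinal_bias_amplitude=5.0,
        response_noise_sd=2.0, noise_sd_cardinal_modulation=0.5,
        swap_rate=0.0, outlier_rate=0.0, include_trajectories=False, seed=29)
    trials, _, _ = sb.simulate_experiment(cfg)
    corrected, _ = sb.correct_trials(trials)
    ok = ~corrected["error_outlier"]
    bins = (corrected.loc[ok, "target"] // 22.5).astype(int)
    binned = corrected.loc[ok].groupby(bins)["corrected_error"].mean()
    assert np.abs(binned).max() < max(0.5, 0.1 * cfg.cardinal_bias_amplitude)


def test_correction_does_not_inject_serial_structure():
    """On bias-free data the density asymmetry is unchanged (within Monte
    Carlo error) by the correction step."""
    cfg = sb.SimulationConfig(
        n_participants=6, n_trials_per_condition=480, block_size=96,
        bias_amplitude_mean_by_condition={"Stroop": 0.0, "NoStroop": 0.0},
        bias_amplitude_sd=0.0, swap_rate=0.0, outlier_rate=0.0,
        include_trajectories=False, seed=13)
    trials, _, _ = sb.simulate_experiment(cfg)
    df = sb.add_previous_context(trials)
    ok = df["valid_prev"] & df["delta_prev"].ne(0.0) & df["delta_prev"].notna()
    raw = sb.density_asymmetry(toward_previous_sign(
        df.loc[ok, "error"].to_numpy(), df.loc[ok, "delta_prev"].to_numpy()))
    corrected, _ = sb.correct_trials(trials)
    est, _ = sb.per_subject_bias(sb.add_previous_context(corrected))
    pooled = 100.0 * ((est.n_toward.sum() - est.n_away.sum())
                      / (est.n_toward.sum() + est.n_away.sum()))
    assert abs(pooled - raw.asymmetry) < 3.0


def test_model_serialization_roundtrip():
    rng = np.random.default_rng(8)
    theta = rng.uniform(0, 360, 2000)
    err = _sin4(theta, 3.0) + rng.normal(0, 2, len(theta))
    model = an.select_scheme(theta, err)
    d = model.to_dict()
    assert d["scheme"] in ("cardinal", "oblique")
    assert len(d["polynomial_coefficients"]) == 4
    assert all(len(c) == 5 for c in d["polynomial_coefficients"])
    assert model.predict_sd(np.linspace(0, 359, 100)).min() > 0
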