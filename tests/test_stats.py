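import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import serialbias as sb
from serialbias.stats import (one_sample_t, paired_t, rt_dissimilarity_model,
                              stroop_congruency_contrast, within_subject_ci)


def test_t_computations_match_textbook_oracle():
    """t, p, CI of the wrappers match the explicit formulas to 1e-10."""
    rng = np.random.default_rng(0)
    for n in (5, 12, 33):
        for _ in range(5):
            x = rng.normal(0.3, 1.7, n)
            res = one_sample_t(x)
            mean, sd = x.mean(), x.std(ddof=1)
            t = mean / (sd / np.sqrt(n))
            p = 2 * sps.t.sf(abs(t), n - 1)
            half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)
            assert res.ci_low == pytest.approx(mean - half, abs=1e-10)
            assert res.d == pytest.approx(mean / sd, abs=1e-10)
            assert res.ci_low < res.mean < res.ci_high

            a, b = rng.normal(0, 1, n), rng.normal(0.2, 1, n)
            pres = paired_t(a, b)
            ref = sps.ttest_rel(a, b)
            assert pres.t == pytest.approx(ref.statistic, abs=1e-10)
            assert pres.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert pres.df == n - 1
            assert pres.d == pytest.approx((a - b).mean() / (a - b).std(ddof=1),
                                           abs=1e-10)


def test_within_subject_ci_zero_interaction_variance():
    """Two conditions that differ by a constant per subject have ~zero-width
    within-subject CIs."""
    rng = np.random.default_rng(1)
    base = rng.normal(0, 5, 12)
    m = pd.DataFrame({"a": base, "b": base + 3.0})
    ci = within_subject_ci(m)
    assert (ci["ci_high"] - ci["ci_low"]).max() < 1e-9


def test_within_subject_ci_single_condition_falls_back():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 2, 15)
    ci = within_subject_ci(pd.DataFrame({"only": x}))
    ref = one_sample_t(x)
    assert ci.loc[0, "ci_low"] == pytest.approx(ref.ci_low)
    assert ci.loc[0, "ci_high"] == pytest.approx(ref.ci_high)


def test_within_subject_ci_difference_coverage():
    """For C=2 the adjusted SEs reproduce the paired-difference CI, so the
    implied difference interval has nominal coverage."""
    rng = np.random.default_rng(3)
    n, true_diff, cover = 20, 0.0, 0
    reps = 400
    for _ in range(reps):
        subj = rng.normal(0, 2, n)
        a = subj + rng.normal(0, 1, n)
        b = subj + true_diff + rng.normal(0, 1, n)
        ci = within_subject_ci(pd.DataFrame({"a": a, "b": b}))
        half = sps.t.ppf(0.975, n - 1) * np.sqrt((ci["se"] ** 2).sum())
        diff = a.mean() - b.mean()
        cover += (diff - half <= true_diff <= diff + half)
    assert 0.92 <= cover / reps <= 0.98


def test_stroop_contrast_signs_and_nulls(small_corrected):
    _, paired, _, _, _ = small_corrected
    res = stroop_congruency_contrast(paired)
    stroop = res["Stroop"]
    assert stroop["rt"].mean_a < stroop["rt"].mean_b  # congruent faster
    assert stroop["rt"].p < 0.05
    assert stroop["accuracy"].mean_a > stroop["accuracy"].mean_b
    # fixed-key condition: no congruency effect on RT
    assert res["NoStroop"]["rt"].p > 0.005


def test_stroop_contrast_requires_labels():
    df = pd.DataFrame({"participant": [1], "condition": ["Stroop"]})
    with pytest.raises(ValueError, match="stroop"):
        stroop_congruency_contrast(df)


def test_condition_bias_contrast_perfect_coupling():
    rng = np.random.default_rng(4)
    vals = rng.normal(0, 3, 20)
    est = pd.DataFrame({
        "participant": list(range(20)) * 2,
        "condition": ["Stroop"] * 20 + ["NoStroop"] * 20,
        "asymmetry": np.concatenate([vals + 2, vals - 2]),
    })
    res = sb.condition_bias_contrast(est)
    assert res["correlation"]["r"] == pytest.approx(1.0)
    # conditions are compared in sorted label order: NoStroop - Stroop
    assert res["contrast"].labels == ("NoStroop", "Stroop")
    assert res["contrast"].mean_diff == pytest.approx(-4.0)
    assert res["contrast"].p < 1e-6


def test_rt_model_recovers_injected_slope_and_is_shift_equivariant():
    cfg = sb.SimulationConfig(n_participants=12, include_trajectories=False,
                              seed=17)
    trials, _, _ = sb.simulate_experiment(cfg)
    fit = rt_dissimilarity_model(trials)
    assert fit.method == "two_stage"
    assert fit.slope.mean == pytest.approx(cfg.rt_slope_per_degree, abs=0.3)
    assert fit.slope.ci_low < fit.slope.mean < fit.slope.ci_high
    # offset recovered (NoStroop is the second condition alphabetically...
    # conditions order comes from sorted labels: NoStroop < Stroop)
    # cond2 indicator marks the second sorted label = "Stroop", which is
    # -66 ms relative to NoStroop
    assert fit.condition_offset.mean == pytest.approx(-cfg.rt_condition_offset,
                                                      abs=25.0)
    assert fit.interaction.ci_low < 0 < fit.interaction.ci_high

    shifted = trials.assign(report_rt=trials["report_rt"] + 0.5)
    fit2 = rt_dissimilarity_model(shifted)
    assert fit2.intercept.mean == pytest.approx(fit.intercept.mean + 500.0,
                                                abs=1e-6)
    assert fit2.slope.mean == pytest.approx(fit.slope.mean, abs=1e-9)
    assert fit2.condition_offset.mean == pytest.approx(
        fit.condition_offset.mean, abs=1e-9)


def test_rt_model_excludes_sparse_participants(caplog):
    cfg = sb.SimulationConfig(n_participants=5, n_trials_per_condition=96,
                              block_size=96, include_trajectories=False,
                              seed=19)
    trials, _, _ = sb.simulate_experiment(cfg)
    # cripple participant 5: keep only 3 trials per condition
    keep = (trials["participant"] != 5) | (trials["trial_index"] < 3)
    fit = rt_dissimilarity_model(trials[keep])
    assert fit.n_excluded == 1
    assert len(fit.per_participant) == 4


def test_rt_model_mixed_route_agrees_with_two_stage():
    cfg = sb.SimulationConfig(n_participants=10, n_trials_per_condition=192,
                              block_size=96, include_trajectories=False,
                              seed=23)
    trials, _, _ = sb.simulate_experiment(cfg)
    two = rt_dissimilarity_model(trials, method="two_stage")
    mixed = rt_dissimilarity_model(trials, method="mixed")
    assert mixed.method == "mixed"
    assert mixed.slope.mean == pytest.approx(two.slope.mean, abs=0.15)
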