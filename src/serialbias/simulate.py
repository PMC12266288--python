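"""Synthetic direction-report experiments with a known ground truth.

The generator emulates the statistical structure of a dual-task continuous
direction-report study: a teardrop stimulus pointing in a uniformly random
direction is remembered across a delay occupied (or not) by a color-word
Stroop task, and reported by rotating a probe with the mouse. It produces

* a trial table (one row per trial: target, report, report RT, Stroop
  word/color/response/RT),
* an optional trajectory table (one row per polled cursor sample), and
* a :class:`GroundTruth` record of every injected parameter,

so that each downstream analysis stage has a known acceptance surface.

Injected effects
----------------
* serial bias toward/away from the previous target with a
  derivative-of-Gaussian (DoG) dissimilarity tuning
  ``b(delta) = a * (delta/w) * exp(-(delta/w)**2)``, with a per-subject
  amplitude drawn from a bivariate normal so the amplitude is correlated
  across conditions;
* cardinal anisotropy of the response (attraction to or repulsion from the
  cardinal directions) plus a response-noise SD that varies with distance to
  the nearest cardinal;
* report RT decreasing linearly with current-previous dissimilarity, with a
  condition offset and per-subject intercept/slope variation;
* Stroop congruency effects on RT and accuracy (and a constant-key,
  chance-accuracy "response" in the No Stroop condition);
* occasional swap errors (report near the previous target) and uniform
  outliers;
* response trajectories that start from a noisy initial angle whose bias sign
  agrees with the trial's final bias sign with a configurable probability,
  pass through an early repulsive lobe peaked at intermediate dissimilarity,
  and decay into the final report (the last sample reproduces the report
  exactly).

Amplitude units: the per-condition serial-bias amplitude is given either in
asymmetry percentage points (``bias_amplitude_unit="percent"``, the scale on
which group results are reported; converted internally to DoG degrees via a
small-bias linearization under the configured noise model) or directly as the
DoG peak-slope amplitude in degrees (``"degrees"``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import wrap_direction, wrap_signed, signed_diff

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_experiment",
    "simulate_stroop_block",
    "save_simulation",
    "dog_bias",
    "cardinal_bias_profile",
]

_COLORS = ("red", "green", "blue")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic experiment.

    Defaults reproduce the study scale: 33 analyzed participants, two
    within-subject conditions of 5 blocks x 96 trials, study-level effect
    sizes (group asymmetries +1.90% with Stroop, -1.61% without, amplitude
    correlation 0.7 across conditions, RT slope -0.88 ms/deg, Stroop
    congruency effects of 40 ms and 1.5 accuracy points).
    """

    n_participants: int = 33
    n_trials_per_condition: int = 480
    block_size: int = 96
    conditions: tuple = ("Stroop", "NoStroop")

    # serial bias
    bias_amplitude_mean_by_condition: dict = field(
        default_factory=lambda: {"Stroop": 1.90, "NoStroop": -1.61}
    )
    bias_amplitude_sd: float = 3.0
    bias_amplitude_unit: str = "percent"  # or "degrees"
    cross_condition_correlation: float = 0.7
    bias_tuning_width: float = 40.0

    # cardinal anisotropy + response noise
    cardinal_bias_amplitude: float = 5.0
    cardinal_bias_sign: str = "repel"  # or "attract"
    cardinal_bias_shape: str = "sin4"  # or "local"
    cardinal_bias_width: float = 30.0  # only for shape="local"
    response_noise_sd: float = 9.0
    noise_sd_cardinal_modulation: float = 3.0

    # contaminants
    swap_rate: float = 0.01
    outlier_rate: float = 0.005

    # report RT model (seconds / ms)
    rt_intercept: float = 0.96
    rt_slope_per_degree: float = -0.88  # ms per degree of dissimilarity
    rt_condition_offset: float = 66.0  # ms added in the No Stroop condition
    rt_subject_sd: float = 0.15
    rt_slope_subject_sd: float = 0.2  # ms/deg
    rt_noise_sd: float = 0.25
    rt_floor: float = 0.2

    # Stroop task
    stroop_congruency_rt_effect: float = 0.04
    stroop_accuracy: float = 0.92
    stroop_congruency_acc_effect: float = 0.015
    stroop_rt_mean: float = 0.64
    stroop_rt_sd: float = 0.10
    nostroop_rt_mean: float = 0.38

    # response trajectories
    include_trajectories: bool = True
    trajectory_sample_rate: float = 60.0  # Hz
    trajectory_duration_mean: float | None = None  # None -> per-trial report RT
    early_bias_amplitude: float = 6.0  # degrees (repulsive lobe depth)
    early_bias_peak_dissimilarity: float = 80.0
    early_bias_trial_sd: float = 3.0
    trajectory_ramp: float = 0.8  # s over which the early lobe decays
    trajectory_jitter_sd: float = 5.0
    initial_angle_noise: float = 25.0
    first_frame_agreement: float = 0.61
    second_frame_repulsive_rate: float = 0.4297

    seed: int = 0

    def __post_init__(self):
        if int(self.n_participants) < 1:
            raise ValueError("n_participants must be >= 1")
        if int(self.n_trials_per_condition) < 2:
            raise ValueError("n_trials_per_condition must be >= 2")
        if int(self.block_size) < 2:
            raise ValueError("block_size must be >= 2")
        if len(self.conditions) != 2:
            raise ValueError("conditions must name exactly two conditions")
        missing = [c for c in self.conditions
                   if c not in self.bias_amplitude_mean_by_condition]
        if missing:
            raise ValueError(
                f"bias_amplitude_mean_by_condition missing condition(s) {missing}")
        if self.bias_amplitude_unit not in ("percent", "degrees"):
            raise ValueError("bias_amplitude_unit must be 'percent' or 'degrees'")
        if not -1.0 <= self.cross_condition_correlation <= 1.0:
            raise ValueError("cross_condition_correlation must be in [-1, 1]")
        for name in ("bias_amplitude_sd", "bias_tuning_width", "response_noise_sd",
                     "noise_sd_cardinal_modulation", "rt_subject_sd",
                     "rt_slope_subject_sd", "rt_noise_sd", "stroop_rt_sd",
                     "early_bias_trial_sd", "trajectory_jitter_sd",
                     "initial_angle_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("swap_rate", "outlier_rate", "stroop_accuracy",
                     "first_frame_agreement", "second_frame_repulsive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.trajectory_sample_rate <= 0:
            raise ValueError("trajectory_sample_rate must be > 0")
        if self.bias_tuning_width <= 0:
            raise ValueError("bias_tuning_width must be > 0")
        if self.early_bias_peak_dissimilarity <= 0:
            raise ValueError("early_bias_peak_dissimilarity must be > 0")
        if self.trajectory_ramp <= 0:
            raise ValueError("trajectory_ramp must be > 0")
        if self.cardinal_bias_sign not in ("attract", "repel"):
            raise ValueError("cardinal_bias_sign must be 'attract' or 'repel'")
        if self.cardinal_bias_shape not in ("sin4", "local"):
            raise ValueError("cardinal_bias_shape must be 'sin4' or 'local'")
        if self.bias_amplitude_unit == "percent" and self.response_noise_sd == 0:
            raise ValueError(
                "bias_amplitude_unit='percent' requires response_noise_sd > 0 "
                "(the percent-to-degrees conversion diverges at zero noise)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d


@dataclass
class GroundTruth:
    """Every injected parameter of a simulated experiment."""

    config: SimulationConfig
    subjects: pd.DataFrame  # participant x condition amplitudes and RT effects
    percent_per_degree: float  # asymmetry %-points per degree of DoG amplitude

    def to_json(self, path=None) -> str:
        payload = {
            "config": self.config.to_dict(),
            "percent_per_degree": self.percent_per_degree,
            "subjects": self.subjects.to_dict(orient="list"),
        }
        text = json.dumps(payload, sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def dog_bias(delta, amplitude_deg, width):
    """Derivative-of-Gaussian serial-bias profile, odd in the signed
    previous-minus-current difference ``delta``."""
    d = np.asarray(delta, dtype=float)
    x = d / width
    return amplitude_deg * x * np.exp(-x * x)


def cardinal_bias_profile(theta, config: SimulationConfig):
    """Signed error (degrees) injected at direction ``theta`` by the cardinal
    anisotropy.

    ``shape="sin4"``: amplitude * sin(4*theta), sign +1 for repulsion from
    cardinals (error grows away from the cardinal) and -1 for attraction.
    ``shape="local"``: a profile of the signed distance ``d`` to the nearest
    cardinal — V-shaped ``sign(d)*exp(-|d|/tau)`` for repulsion (discontinuous
    at cardinals) or a smooth DoG ``-(d/tau)*exp((1-(d/tau)^2)/2)`` for
    attraction.
    """
    th = np.asarray(theta, dtype=float)
    a = config.cardinal_bias_amplitude
    s = 1.0 if config.cardinal_bias_sign == "repel" else -1.0
    if config.cardinal_bias_shape == "sin4":
        return s * a * np.sin(np.deg2rad(4.0 * th))
    d = (th + 45.0) % 90.0 - 45.0
    tau = config.cardinal_bias_width
    if config.cardinal_bias_sign == "repel":
        return a * np.sign(d) * np.exp(-np.abs(d) / tau)
    x = d / tau
    return -a * x * np.exp((1.0 - x * x) / 2.0)


def noise_sd_profile(theta, config: SimulationConfig):
    """Response-noise SD at direction ``theta``: the base SD at cardinals,
    increased by the cosine modulation toward obliques (the oblique effect)."""
    th = np.asarray(theta, dtype=float)
    mod = config.noise_sd_cardinal_modulation
    return config.response_noise_sd + mod * (1.0 - np.cos(np.deg2rad(4.0 * th))) / 2.0


def early_lobe_profile(dissimilarity, config: SimulationConfig):
    """Early repulsive trajectory lobe (degrees, toward-coded, <= 0), peaked at
    ``early_bias_peak_dissimilarity`` with depth ``early_bias_amplitude``."""
    d = np.asarray(dissimilarity, dtype=float)
    p = config.early_bias_peak_dissimilarity
    x = d / p
    return -config.early_bias_amplitude * x * np.exp((1.0 - x * x) / 2.0)


def percent_per_degree(config: SimulationConfig) -> float:
    """Asymmetry percentage points produced per degree of DoG amplitude.

    Small-bias linearization: a toward-shift ``b`` against noise SD ``sigma``
    yields an expected sign asymmetry ``100*(2*Phi(b/sigma)-1) ~=
    100*sqrt(2/pi)*b/sigma``; averaged over uniform dissimilarity (DoG
    profile) and uniform direction (heteroscedastic noise profile).
    """
    delta = np.linspace(0.25, 180.0, 720)
    mean_dog = float(np.mean(dog_bias(delta, 1.0, config.bias_tuning_width)))
    theta = np.linspace(0.0, 360.0, 1441)[:-1]
    mean_inv_sigma = float(np.mean(1.0 / noise_sd_profile(theta, config)))
    return 100.0 * np.sqrt(2.0 / np.pi) * mean_dog * mean_inv_sigma


def _draw_subject_amplitudes(config: SimulationConfig, rng) -> pd.DataFrame:
    """Per-subject serial-bias amplitudes, correlated across conditions."""
    c1, c2 = config.conditions
    m = np.array([config.bias_amplitude_mean_by_condition[c1],
                  config.bias_amplitude_mean_by_condition[c2]])
    s = config.bias_amplitude_sd
    rho = config.cross_condition_correlation
    cov = s * s * np.array([[1.0, rho], [rho, 1.0]])
    amp = rng.multivariate_normal(m, cov, size=config.n_participants)

    if config.bias_amplitude_unit == "percent":
        k = percent_per_degree(config)
        amp_pct = amp
        amp_deg = amp / k
    else:
        k = percent_per_degree(config) if config.response_noise_sd > 0 else np.nan
        amp_deg = amp
        amp_pct = amp * k
    rows = []
    rt_int = rng.normal(0.0, config.rt_subject_sd, size=config.n_participants)
    rt_slope = rng.normal(0.0, config.rt_slope_subject_sd,
                          size=config.n_participants)
    for i in range(config.n_participants):
        for j, cond in enumerate(config.conditions):
            rows.append({
                "participant": i + 1,
                "condition": cond,
                "bias_amplitude_pct": amp_pct[i, j],
                "bias_amplitude_deg": amp_deg[i, j],
                "rt_subject_intercept": rt_int[i],
                "rt_subject_slope": rt_slope[i],
            })
    return pd.DataFrame(rows)


def simulate_stroop_block(config: SimulationConfig, n_trials: int,
                          condition: str, rng) -> pd.DataFrame:
    """Stroop word/color/response/RT columns for one block of trials.

    In the Stroop condition congruent trials (word matches color) are faster
    by ``stroop_congruency_rt_effect`` and more accurate by
    ``stroop_congruency_acc_effect``; in the No Stroop condition the response
    is the fixed down-arrow key (coded as ``green``) regardless of the
    stimulus, so "accuracy" relative to the color sits near chance.
    """
    word = rng.choice(_COLORS, size=n_trials)
    color = rng.choice(_COLORS, size=n_trials)
    congruent = word == color
    if condition == config.conditions[0]:  # Stroop condition
        eff = config.stroop_congruency_acc_effect
        # split so the trial-weighted mean accuracy equals stroop_accuracy
        acc = np.where(congruent,
                       config.stroop_accuracy + 2.0 * eff / 3.0,
                       config.stroop_accuracy - eff / 3.0)
        correct = rng.random(n_trials) < acc
        response = np.where(correct, color, "")
        wrong = ~correct
        if wrong.any():
            # pick one of the two other colors uniformly
            others = np.array([[c for c in _COLORS if c != col] for col in color[wrong]])
            pick = rng.integers(0, 2, size=int(wrong.sum()))
            response[wrong] = others[np.arange(len(pick)), pick]
        rt = (config.stroop_rt_mean
              + np.where(congruent, -1.0, 1.0) * config.stroop_congruency_rt_effect / 2.0
              + rng.normal(0.0, config.stroop_rt_sd, size=n_trials))
        rt = np.clip(rt, 0.05, 1.2)
    else:
        response = np.full(n_trials, "green")  # the down-arrow key
        correct = response == color
        rt = np.clip(config.nostroop_rt_mean
                     + rng.normal(0.0, config.stroop_rt_sd, size=n_trials),
                     0.05, 1.2)
    return pd.DataFrame({
        "stroop_word": word,
        "stroop_color": color,
        "stroop_congruent": congruent,
        "stroop_response": response,
        "stroop_correct": response == color,
        "stroop_rt": rt,
    })


def _simulate_trajectories(trials: pd.DataFrame, config: SimulationConfig,
                           rng) -> pd.DataFrame:
    """Cursor pointing-angle samples for every trial in ``trials``.

    The toward-coded deviation at response-locked time t follows a two-segment
    profile: an early repulsive lobe (plus trial-level jitter) that decays
    linearly over ``trajectory_ramp`` seconds into the trial's final response
    error. The first sample's deviation sign agrees with the final bias sign
    with probability ``first_frame_agreement``; on trials ending attractive,
    the second sample is repulsive with probability
    ``second_frame_repulsive_rate``. The last sample equals the report exactly.
    """
    rate = config.trajectory_sample_rate
    rt = trials["report_rt"].to_numpy()
    if config.trajectory_duration_mean is not None:
        dur = np.full_like(rt, float(config.trajectory_duration_mean))
    else:
        dur = rt
    n_reg = np.floor(dur * rate).astype(int) + 1  # samples at 0, 1/rate, ...
    # keep the regular grid strictly below the response time so the appended
    # final sample never duplicates a time stamp
    on_edge = (n_reg - 1) / rate >= dur - 1e-12
    n_reg[on_edge] -= 1
    n_reg = np.maximum(n_reg, 1)
    m = n_reg + 1                                 # plus the final sample at dur
    total = int(m.sum())
    trial_row = np.repeat(np.arange(len(trials)), m)
    offsets = np.concatenate(([0], np.cumsum(m)[:-1]))
    within = np.arange(total) - np.repeat(offsets, m)
    t = within / rate
    is_last = within == (m[trial_row] - 1)
    t[is_last] = dur[trial_row[is_last]]
    dur_s = dur[trial_row]
    ttr = t - dur_s  # time to response, <= 0

    target = trials["target"].to_numpy()[trial_row]
    delta = trials["delta_prev"].to_numpy()
    sign_delta = np.sign(np.nan_to_num(delta, nan=1.0))
    sign_delta[sign_delta == 0] = 1.0
    diss = np.abs(np.nan_to_num(delta, nan=90.0))
    # the cardinal anisotropy shifts the pointing angle throughout the
    # response, so the toward-coded profile is built around target + card
    card = cardinal_bias_profile(trials["target"].to_numpy(), config)
    e_signed = wrap_signed(trials["report"].to_numpy() - trials["target"].to_numpy())
    e_toward = (e_signed - card) * sign_delta

    lobe = early_lobe_profile(diss, config) + rng.normal(
        0.0, config.early_bias_trial_sd, size=len(trials))
    # quadratic ramp: the final-bias segment dominates the last ~200 ms,
    # confining the terminal bias near the response as in the reported pattern
    w = np.clip(-ttr / config.trajectory_ramp, 0.0, 1.0) ** 2
    dev = (w * lobe[trial_row]
           + (1.0 - w) * e_toward[trial_row]
           + w * rng.normal(0.0, config.trajectory_jitter_sd, size=total))

    # first frame: noisy magnitude, sign coupled to the final bias sign
    first = within == 0
    agree = rng.random(len(trials)) < config.first_frame_agreement
    s1 = np.sign(e_toward) * np.where(agree, 1.0, -1.0)
    s1[s1 == 0] = 1.0
    dev[first] = s1[trial_row[first]] * np.abs(
        rng.normal(0.0, config.initial_angle_noise, size=int(first.sum())))

    # second frame: on attractive-ending trials, flip to repulsion at the
    # configured rate
    second = within == 1
    flip = rng.random(len(trials)) < config.second_frame_repulsive_rate
    s2 = np.where(e_toward > 0, np.where(flip, -1.0, 1.0), np.sign(dev[second]))
    s2[s2 == 0] = 1.0
    dev[second] = s2[trial_row[second]] * np.abs(dev[second])

    pointing = wrap_direction(target + card[trial_row]
                              + dev * sign_delta[trial_row])
    pointing[is_last] = trials["report"].to_numpy()[trial_row[is_last]]

    return pd.DataFrame({
        "participant": trials["participant"].to_numpy()[trial_row],
        "condition": pd.Categorical(trials["condition"].to_numpy()[trial_row]),
        "trial_index": trials["trial_index"].to_numpy()[trial_row],
        "time_from_start": t,
        "time_to_response": ttr,
        "pointing_angle": pointing,
    })


def simulate_experiment(config: SimulationConfig):
    """Simulate a complete experiment.

    Returns ``(trials, trajectories, ground_truth)``; ``trajectories`` is
    ``None`` when ``config.include_trajectories`` is false. All randomness
    flows from the single ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _draw_subject_amplitudes(config, rng)
    amp_deg = subjects.set_index(["participant", "condition"])["bias_amplitude_deg"]

    n = config.n_trials_per_condition
    frames = []
    for p in range(1, config.n_participants + 1):
        rt_int = subjects.loc[subjects.participant == p, "rt_subject_intercept"].iloc[0]
        rt_slo = subjects.loc[subjects.participant == p, "rt_subject_slope"].iloc[0]
        for cond in config.conditions:
            a = amp_deg.loc[(p, cond)]
            target = rng.uniform(0.0, 360.0, size=n)
            block = np.arange(n) // config.block_size
            prev = np.roll(target, 1)
            first_of_block = np.zeros(n, dtype=bool)
            first_of_block[0] = True
            first_of_block[1:] = block[1:] != block[:-1]
            delta = signed_diff(prev, target)
            delta[first_of_block] = np.nan

            serial = dog_bias(np.nan_to_num(delta, nan=0.0), a,
                              config.bias_tuning_width)
            card = cardinal_bias_profile(target, config)
            sd = noise_sd_profile(target, config)
            noise = rng.normal(0.0, 1.0, size=n) * sd
            report = wrap_direction(target + serial + card + noise)

            swap = (rng.random(n) < config.swap_rate) & ~first_of_block
            if swap.any():
                report[swap] = wrap_direction(
                    prev[swap] + rng.normal(0.0, config.response_noise_sd,
                                            size=int(swap.sum())))
            outl = rng.random(n) < config.outlier_rate
            if outl.any():
                report[outl] = rng.uniform(0.0, 360.0, size=int(outl.sum()))

            diss = np.abs(np.nan_to_num(delta, nan=90.0))
            rt = (config.rt_intercept + rt_int
                  + (config.rt_slope_per_degree + rt_slo) / 1000.0 * diss
                  + (config.rt_condition_offset / 1000.0
                     if cond == config.conditions[1] else 0.0)
                  + rng.normal(0.0, config.rt_noise_sd, size=n))
            rt = np.maximum(rt, config.rt_floor)

            stroop = simulate_stroop_block(config, n, cond, rng)
            df = pd.DataFrame({
                "participant": p,
                "condition": cond,
                "block": block,
                "trial_index": np.arange(n),
                "is_practice": False,
                "target": target,
                "report": report,
                "report_rt": rt,
                "prev_target": prev,
                "delta_prev": delta,
                "gt_swap": swap,
                "gt_outlier": outl,
            })
            frames.append(pd.concat([df, stroop], axis=1))

    trials = pd.concat(frames, ignore_index=True)
    trials["error"] = wrap_signed(trials["report"].to_numpy()
                                  - trials["target"].to_numpy())

    trajectories = None
    if config.include_trajectories:
        trajectories = _simulate_trajectories(trials, config, rng)

    gt = GroundTruth(
        config=config,
        subjects=subjects,
        percent_per_degree=(percent_per_degree(config)
                            if config.response_noise_sd > 0 else float("nan")),
    )
    return trials, trajectories, gt


def save_simulation(out_dir, trials: pd.DataFrame,
                    trajectories: pd.DataFrame | None,
                    ground_truth: GroundTruth) -> dict:
    """Write the simulated tables (CSV), ground truth (JSON) and config (YAML)."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"trials": out / "trials.csv", "ground_truth": out / "ground_truth.json",
             "config": out / "config.yaml"}
    trials.to_csv(paths["trials"], index=False)
    if trajectories is not None:
        paths["trajectories"] = out / "trajectories.csv"
        trajectories.to_csv(paths["trajectories"], index=False)
    ground_truth.to_json(paths["ground_truth"])
    paths["config"].write_text(yaml.safe_dump(ground_truth.config.to_dict()))
    return {k: str(v) for k, v in paths.items()}
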