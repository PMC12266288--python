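"""End-to-end analysis pipeline.

Composes the stages in analysis order — simulate or ingest, anisotropy
correction, serial-bias estimation (scalar + dissimilarity curve), trajectory
bias surfaces and frame-sign analyses, Stroop and RT statistics — and writes
a machine-readable JSON report plus a short human-readable summary. Every
stage logs trials in / used / excluded, and a fixed seed yields a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import anisotropy, bias, stats, trajectory
from .simulate import SimulationConfig, simulate_experiment

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    Exactly one input source: either ``simulation`` (a
    :class:`~serialbias.simulate.SimulationConfig`) or ``trials_csv`` (with
    ``trajectories_csv`` if the trajectory stage is enabled).
    """

    simulation: SimulationConfig | None = None
    trials_csv: str | None = None
    trajectories_csv: str | None = None
    out_dir: str | None = None

    time_kernel_sd_ms: float = 120.0
    diss_kernel_sd: float = 20.0
    grid_size: int = 90
    min_trials_per_frame: int = 20
    rolling_kernel_sd: float = 20.0
    min_per_bin: int = 25
    alpha: float = 0.05
    surface_unit: str = "degrees"
    rt_method: str = "two_stage"
    run_trajectory: bool = True
    verbosity: str = "WARNING"

    def __post_init__(self):
        if (self.simulation is None) == (self.trials_csv is None):
            raise ValueError("provide exactly one input source: "
                             "simulation or trials_csv")
        for name in ("time_kernel_sd_ms", "diss_kernel_sd", "rolling_kernel_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "conditions" in sim:
                sim["conditions"] = tuple(sim["conditions"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def _jsonify(obj):
    """Recursively convert results into JSON-serializable structures."""
    if is_dataclass(obj) and hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    if is_dataclass(obj):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.tolist())
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _stage(report, name, n_in, n_used):
    entry = {"trials_in": int(n_in), "trials_used": int(n_used),
             "trials_excluded": int(n_in - n_used)}
    assert entry["trials_in"] == entry["trials_used"] + entry["trials_excluded"]
    report["stages"][name] = entry
    logger.info("stage %-12s in=%d used=%d excluded=%d", name,
                n_in, n_used, n_in - n_used)


def _group_bias_curve(coded: pd.DataFrame, kernel_sd: float, alpha: float):
    """Across-participant mean bias curve per condition with pointwise
    one-sample t-tests (uncorrected, as in a per-step significance readout)."""
    grid = np.linspace(0.0, 180.0, 91)
    out = {}
    for cond, sub in coded.groupby("condition", observed=True):
        curves = []
        for _, grp in sub.groupby("participant"):
            c = bias.rolling_asymmetry(grp["toward_error"].to_numpy(),
                                       grp["dissimilarity"].to_numpy(),
                                       kernel_sd=kernel_sd, grid=grid)
            curves.append(np.where(c.supported, c.asymmetry, np.nan))
        arr = np.vstack(curves)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(arr, axis=0)
            tres = sps.ttest_1samp(arr, 0.0, axis=0, nan_policy="omit")
        pvals = np.asarray(tres.pvalue, dtype=float)
        sig = np.isfinite(pvals) & (pvals < alpha)
        sig_points = grid[sig]
        out[str(cond)] = {
            "grid_deg": grid,
            "mean_asymmetry_pct": mean,
            "t": np.asarray(tres.statistic, dtype=float),
            "p": pvals,
            "significant_range_deg": ([float(sig_points.min()),
                                       float(sig_points.max())]
                                      if sig_points.size else None),
            "n_participants": int(sub["participant"].nunique()),
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the report dictionary.

    If ``config.out_dir`` is set, writes ``report.json``, ``summary.txt``,
    the corrected trial table, per-subject bias estimates, bias curves and
    (when the trajectory stage runs) one surface CSV + metadata per condition.
    """
    logging.basicConfig()
    logging.getLogger("serialbias").setLevel(config.verbosity)
    report = {"stages": {}}

    # -- ingest or simulate ------------------------------------------------
    stage = "ingest"
    try:
        if config.simulation is not None:
            trials, traj, gt = simulate_experiment(config.simulation)
            report["input"] = {"source": "simulation",
                               "seed": config.simulation.seed}
        else:
            tpath = Path(config.trials_csv)
            if not tpath.exists():
                raise FileNotFoundError(f"trial file not found: {tpath}")
            trials = pd.read_csv(tpath)
            traj = None
            if config.run_trajectory:
                if config.trajectories_csv is None:
                    raise FileNotFoundError(
                        "trajectory stage enabled but no trajectories_csv given")
                trpath = Path(config.trajectories_csv)
                if not trpath.exists():
                    raise FileNotFoundError(f"trajectory file not found: {trpath}")
                traj = pd.read_csv(trpath)
            report["input"] = {"source": str(tpath), "seed": None}
        if "is_practice" in trials.columns:
            n0 = len(trials)
            trials = trials[~trials["is_practice"]].copy()
            _stage(report, stage, n0, len(trials))
        else:
            _stage(report, stage, len(trials), len(trials))
    except Exception as e:
        raise PipelineError(f"stage '{stage}' failed: {e}") from e

    # -- anisotropy correction --------------------------------------------
    stage = "anisotropy"
    try:
        corrected, models = anisotropy.correct_trials(
            trials, min_per_bin=config.min_per_bin)
        n_out = int(corrected["error_outlier"].sum())
        _stage(report, stage, len(corrected), len(corrected) - n_out)
        schemes = {p: m.scheme.name for p, m in models.items()}
        report["anisotropy"] = {
            "scheme_counts": {s: int(sum(v == s for v in schemes.values()))
                              for s in ("cardinal", "oblique")},
            "outlier_fraction": n_out / len(corrected),
            "models": {str(p): m.to_dict() for p, m in models.items()},
        }
    except Exception as e:
        raise PipelineError(f"stage '{stage}' failed: {e}") from e

    # -- serial bias --------------------------------------------------------
    stage = "serial_bias"
    try:
        paired = bias.add_previous_context(corrected)
        coded = bias.toward_coded_errors(paired)
        _stage(report, stage, len(paired), len(coded))
        estimates, correlation = bias.per_subject_bias(paired)
        contrast = stats.condition_bias_contrast(estimates)
        report["bias"] = {
            "per_subject": estimates,
            "group": {
                "contrast": contrast["contrast"],
                "per_condition": contrast["per_condition"],
                "within_subject_ci": contrast["within_subject_ci"],
                "correlation": contrast["correlation"],
            },
            "curves": _group_bias_curve(coded, config.rolling_kernel_sd,
                                        config.alpha),
        }
    except Exception as e:
        raise PipelineError(f"stage '{stage}' failed: {e}") from e

    # -- trajectories --------------------------------------------------------
    surfaces = {}
    if config.run_trajectory:
        stage = "trajectory"
        try:
            if traj is None:
                raise FileNotFoundError("trajectory stage enabled but no "
                                        "trajectory table available")
            surfaces = trajectory.trajectory_bias_surface(
                traj, paired, time_sd=config.time_kernel_sd_ms / 1000.0,
                diss_sd=config.diss_kernel_sd, n_grid=config.grid_size,
                min_trials=config.min_trials_per_frame,
                unit=config.surface_unit, alpha=config.alpha)
            frames = trajectory.frame_bias(traj, paired)
            _stage(report, stage, len(paired), int(frames["n_samples"].count()))
            ffa = trajectory.first_frame_sign_analysis(frames)
            model = trajectory.first_last_sign_model(frames)
            second = trajectory.second_frame_repulsive_fraction(frames)
            report["trajectory"] = {
                "surfaces": {
                    cond: {
                        "unit": s.unit,
                        "support_ms": s.support_ms,
                        "n_participants": s.n_participants,
                        "clusters": s.clusters,
                        "extremum_negative": s.extremum(-1),
                        "extremum_positive": s.extremum(+1),
                    } for cond, s in surfaces.items()
                },
                "first_frame": {
                    "strata": {f"{c}|final{'+' if s > 0 else '-'}": r
                               for (c, s), r in ffa["strata"].items()},
                    "condition_contrast": ffa["condition_contrast"],
                },
                "first_last_model": {"mean_slope": float(np.mean(model["slopes"])),
                                     "test": model["test"],
                                     "n_capped": model["n_capped"]},
                "second_frame": second,
            }
        except Exception as e:
            raise PipelineError(f"stage '{stage}' failed: {e}") from e

    # -- inferential stats ---------------------------------------------------
    stage = "stats"
    try:
        report["stroop"] = stats.stroop_congruency_contrast(corrected)
        rt_fit = stats.rt_dissimilarity_model(paired, method=config.rt_method)
        report["rt_model"] = rt_fit.to_dict()
        _stage(report, stage, len(paired),
               int(rt_fit.per_participant["n"].sum()))
    except Exception as e:
        raise PipelineError(f"stage '{stage}' failed: {e}") from e

    report = _jsonify(report)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        corrected.to_csv(out / "corrected_trials.csv", index=False)
        pd.DataFrame(report["bias"]["per_subject"]).to_csv(
            out / "per_subject_bias.csv", index=False)
        for cond, s in surfaces.items():
            tag = str(cond).replace(" ", "_")
            pd.DataFrame(s.bias, index=s.time_grid,
                         columns=s.diss_grid).to_csv(out / f"surface_{tag}.csv")
            meta = {"condition": s.condition, "unit": s.unit,
                    "alpha": s.alpha, "support_ms": s.support_ms,
                    "time_grid_s": s.time_grid.tolist(),
                    "diss_grid_deg": s.diss_grid.tolist(),
                    "clusters": _jsonify(s.clusters)}
            (out / f"surface_{tag}.json").write_text(
                json.dumps(meta, sort_keys=True, indent=2))
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2))
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    """Short human-readable digest of a report."""
    lines = ["serialbias pipeline summary", "=" * 28]
    for name, st in report["stages"].items():
        lines.append(f"{name}: {st['trials_in']} in, {st['trials_used']} used, "
                     f"{st['trials_excluded']} excluded")
    g = report["bias"]["group"]
    for cond, res in g["per_condition"].items():
        lines.append(f"bias[{cond}]: mean {res['mean']:+.2f}% "
                     f"[{res['ci_low']:.2f}, {res['ci_high']:.2f}], "
                     f"t({res['df']}) = {res['t']:.2f}, p = {res['p']:.4g}")
    c = g["contrast"]
    lines.append(f"condition contrast: diff {c['mean_diff']:+.2f}%, "
                 f"t({c['df']}) = {c['t']:.2f}, p = {c['p']:.4g}, d = {c['d']:.2f}")
    r = g["correlation"]
    lines.append(f"cross-condition correlation: r = {r['r']:.3f} "
                 f"(n = {r['n']}, p = {r['p']:.4g})"
                 if r["r"] is not None and r["r"] == r["r"]
                 else "cross-condition correlation: undefined")
    if "trajectory" in report:
        for cond, s in report["trajectory"]["surfaces"].items():
            neg, pos = s["extremum_negative"], s["extremum_positive"]
            lines.append(f"surface[{cond}]: support {s['support_ms']:.0f} ms"
                         + (f", strongest repulsion t = {neg[2]:.2f} at "
                            f"{neg[0]*1000:.0f} ms / {neg[1]:.0f} deg" if neg else "")
                         + (f", strongest attraction t = {pos[2]:.2f} at "
                            f"{pos[0]*1000:.0f} ms / {pos[1]:.0f} deg" if pos else ""))
        sf = report["trajectory"]["second_frame"]
        lines.append(f"second frame repulsive: {sf['percent_repulsive']:.2f}% "
                     f"(n = {sf['n']})")
    rt = report["rt_model"]
    lines.append(f"RT slope: {rt['slope_ms_per_deg']['mean']:.3f} ms/deg "
                 f"[{rt['slope_ms_per_deg']['ci_low']:.3f}, "
                 f"{rt['slope_ms_per_deg']['ci_high']:.3f}]")
    return "\n".join(lines) + "\n"
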