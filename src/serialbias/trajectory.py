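"""Response-locked mouse-trajectory bias analysis.

During the report, the cursor's pointing angle traces how the response
evolves. Two analyses characterize when the response is biased toward or away
from the previous trial's stimulus:

* a **bias surface** over response-locked time (t = 0 at the button press) x
  stimulus dissimilarity, smoothed with Gaussian kernels (SD 120 ms in time,
  20 degrees in dissimilarity) on a 90 x 90 grid, with per-cell one-sample
  t-tests across participants and 4-connected clusters of significant
  same-sign cells;
* **frame-sign analyses** relating the sign (+1 toward / -1 away) of the
  deviation at the very first recorded cursor sample to the sign at the final
  sample of the same trial.

The time axis is truncated to the latest onset at which every participant
still has at least ``min_trials`` trials (long trials are rare, so early
response-locked times are under-sampled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .circular import wrap_signed, toward_previous_sign
from .stats import one_sample_t, paired_t, TTestResult

__all__ = [
    "BiasSurface",
    "trajectory_bias_surface",
    "frame_bias",
    "first_frame_sign_analysis",
    "first_last_sign_model",
    "second_frame_repulsive_fraction",
]

logger = logging.getLogger(__name__)

_TRIAL_KEYS = ["participant", "condition", "trial_index"]


@dataclass
class BiasSurface:
    """Group bias surface over response-locked time x dissimilarity."""

    condition: str
    time_grid: np.ndarray    # seconds, <= 0 (response-locked)
    diss_grid: np.ndarray    # degrees in [0, 180]
    bias: np.ndarray         # time x dissimilarity group mean
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # p < alpha
    cluster_labels: np.ndarray  # 0 = none; >0 positive, <0 negative clusters
    clusters: pd.DataFrame   # id, sign, n_cells, peak time/diss/t
    unit: str                # "degrees" or "percent"
    alpha: float
    support_ms: float        # |earliest supported time|, ms
    n_participants: int

    def extremum(self, sign: int):
        """(time_s, dissimilarity_deg, t) of the strongest significant cell of
        the given sign, or None."""
        sel = self.clusters[self.clusters["sign"] == sign]
        if sel.empty:
            return None
        row = sel.loc[sel["peak_abs_t"].idxmax()]
        return float(row["peak_time_s"]), float(row["peak_diss_deg"]), float(row["peak_t"])


def _usable_trials(trials: pd.DataFrame) -> pd.DataFrame:
    from .bias import add_previous_context

    df = trials if "valid_prev" in trials.columns else add_previous_context(trials)
    ok = df["valid_prev"] & df["delta_prev"].ne(0.0) & df["delta_prev"].notna()
    if "error_outlier" in df.columns:
        ok &= ~df["error_outlier"]
    cols = _TRIAL_KEYS + ["target", "delta_prev", "report_rt"]
    if "predicted_error" in df.columns:
        cols.append("predicted_error")
    return df.loc[ok, cols].copy()


def _toward_deviation(merged: pd.DataFrame) -> np.ndarray:
    dev = wrap_signed(merged["pointing_angle"].to_numpy()
                      - merged["target"].to_numpy()
                      - merged.get("predicted_error",
                                   pd.Series(0.0, index=merged.index)).to_numpy())
    return toward_previous_sign(dev, merged["delta_prev"].to_numpy())


def _participant_surface(ttr, diss, dev, time_grid, diss_grid,
                         time_sd, diss_sd):
    """Kernel-weighted mean toward-coded deviation on the grid for one
    participant (separable Gaussian kernels -> two matrix products)."""
    wt = np.exp(-((ttr[:, None] - time_grid[None, :]) ** 2)
                / (2.0 * time_sd ** 2))
    wd = np.exp(-((diss[:, None] - diss_grid[None, :]) ** 2)
                / (2.0 * diss_sd ** 2))
    num = (wt * dev[:, None]).T @ wd
    den = wt.T @ wd
    out = np.full(den.shape, np.nan)
    good = den > 1e-9
    out[good] = num[good] / den[good]
    return out


def trajectory_bias_surface(trajectories: pd.DataFrame, trials: pd.DataFrame,
                            time_sd: float = 0.120, diss_sd: float = 20.0,
                            n_grid: int = 90, min_trials: int = 20,
                            unit: str = "degrees", alpha: float = 0.05) -> dict:
    """Bias surfaces per condition with per-cell t-tests and clusters.

    ``unit="degrees"`` averages the toward-coded angular deviation itself;
    ``"percent"`` averages its sign scaled to +-100 (the surface analogue of
    the density asymmetry).
    """
    if unit not in ("degrees", "percent"):
        raise ValueError("unit must be 'degrees' or 'percent'")
    use = _usable_trials(trials)
    merged = trajectories.merge(use, on=_TRIAL_KEYS, how="inner")
    if merged.empty:
        raise ValueError("no usable trajectory samples after trial filtering")
    merged["toward_dev"] = _toward_deviation(merged)
    if unit == "percent":
        merged["toward_dev"] = 100.0 * np.sign(merged["toward_dev"])

    surfaces = {}
    for cond, sub in merged.groupby("condition", observed=True):
        # latest onset at which every participant clears min_trials
        durations = sub.groupby(["participant"] + _TRIAL_KEYS[2:],
                                observed=True)["time_from_start"].max()
        bounds = []
        for p, trials_p in durations.groupby("participant"):
            arr = np.sort(trials_p.to_numpy())[::-1]
            if len(arr) < min_trials:
                raise ValueError(
                    f"participant {p} has {len(arr)} usable trials in "
                    f"condition {cond} (< min_trials={min_trials})")
            bounds.append(arr[min_trials - 1])
        support = float(min(bounds))
        if support <= 0:
            raise ValueError(f"no common supported time range in condition {cond}")
        time_grid = np.linspace(-support, 0.0, n_grid)
        diss_grid = np.linspace(0.0, 180.0, n_grid)

        stack = []
        for p, sp in sub.groupby("participant"):
            stack.append(_participant_surface(
                sp["time_to_response"].to_numpy(),
                np.abs(sp["delta_prev"].to_numpy()),
                sp["toward_dev"].to_numpy(),
                time_grid, diss_grid, time_sd, diss_sd))
        stack = np.stack(stack)  # participants x time x dissimilarity

        with np.errstate(invalid="ignore"):
            bias = np.nanmean(stack, axis=0)
            tres = sps.ttest_1samp(stack, 0.0, axis=0, nan_policy="omit")
        tmap = np.asarray(tres.statistic, dtype=float)
        pmap = np.asarray(tres.pvalue, dtype=float)
        sig = np.isfinite(pmap) & (pmap < alpha)

        labels = np.zeros(sig.shape, dtype=int)
        rows = []
        next_id = 1
        for s in (1, -1):
            mask = sig & (np.sign(bias) == s)
            lab, nlab = ndimage.label(mask)  # 4-connected by default
            for k in range(1, nlab + 1):
                cells = lab == k
                labels[cells] = s * next_id
                tt = np.where(cells, tmap, np.nan)
                idx = np.unravel_index(np.nanargmax(np.abs(tt)), tt.shape)
                rows.append({
                    "cluster": s * next_id, "sign": s,
                    "n_cells": int(cells.sum()),
                    "peak_time_s": float(time_grid[idx[0]]),
                    "peak_diss_deg": float(diss_grid[idx[1]]),
                    "peak_t": float(tmap[idx]),
                    "peak_abs_t": float(abs(tmap[idx])),
                })
                next_id += 1
        clusters = pd.DataFrame(
            rows, columns=["cluster", "sign", "n_cells", "peak_time_s",
                           "peak_diss_deg", "peak_t", "peak_abs_t"])

        surfaces[cond] = BiasSurface(
            condition=str(cond), time_grid=time_grid, diss_grid=diss_grid,
            bias=bias, t=tmap, p=pmap, significant=sig, cluster_labels=labels,
            clusters=clusters, unit=unit, alpha=alpha,
            support_ms=support * 1000.0,
            n_participants=int(sub["participant"].nunique()))
    return surfaces


def frame_bias(trajectories: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial toward/away signs at the first, second and last samples.

    Signs are +1 (toward the previous stimulus), -1 (away) or 0 (deviation
    exactly zero / undefined; such trials are excluded by the analyses).
    """
    use = _usable_trials(trials)
    merged = trajectories.merge(use, on=_TRIAL_KEYS, how="inner")
    merged = merged.sort_values(_TRIAL_KEYS + ["time_from_start"],
                                kind="mergesort")
    merged["toward_dev"] = _toward_deviation(merged)
    g = merged.groupby(_TRIAL_KEYS, observed=True)
    merged["sample_rank"] = g.cumcount()
    gd = g["toward_dev"]
    out = pd.DataFrame({
        "n_samples": gd.size(),
        "first_dev": gd.first(),
        "last_dev": gd.last(),
    })
    second = (merged.loc[merged["sample_rank"] == 1]
              .set_index(_TRIAL_KEYS)["toward_dev"])
    out["second_dev"] = second.reindex(out.index)
    out["first_sign"] = np.sign(out["first_dev"])
    out["second_sign"] = np.sign(out["second_dev"])
    out["last_sign"] = np.sign(out["last_dev"])
    return out.reset_index()


def first_frame_sign_analysis(frames: pd.DataFrame) -> dict:
    """First-frame bias sign conditioned on the final-frame bias sign.

    Returns per condition x final-sign stratum the across-participant mean
    first-frame sign with a one-sample t-test against 0, and a paired
    between-condition t-test on each participant's overall mean first-frame
    sign.
    """
    f = frames[(frames["first_sign"] != 0) & (frames["last_sign"] != 0)]
    strata = {}
    cell_means = (f.groupby(["participant", "condition", "last_sign"],
                            observed=True)["first_sign"].mean()
                  .rename("mean_first_sign").reset_index())
    for (cond, s), grp in cell_means.groupby(["condition", "last_sign"],
                                             observed=True):
        vals = grp["mean_first_sign"].to_numpy()
        strata[(str(cond), int(s))] = one_sample_t(vals) if len(vals) >= 2 else None

    overall = (f.groupby(["participant", "condition"], observed=True)["first_sign"]
               .mean().unstack("condition").dropna())
    contrast = None
    if overall.shape[1] == 2 and len(overall) >= 2:
        contrast = paired_t(overall.iloc[:, 0].to_numpy(),
                            overall.iloc[:, 1].to_numpy(),
                            labels=tuple(map(str, overall.columns)))
    return {"strata": strata, "condition_contrast": contrast,
            "participant_means": overall}


def first_last_sign_model(frames: pd.DataFrame, slope_cap: float = 10.0) -> dict:
    """Does the first-frame bias sign predict the final-frame sign?

    Two-stage stand-in for a random-slope logistic GLMM: a per-participant
    logistic regression of (last sign > 0) on the first-frame sign, then a
    one-sample t-test of the slopes against 0. Participants with complete
    separation (or non-converged fits) contribute the capped slope
    ``+-slope_cap`` and are counted in ``n_capped``.
    """
    import statsmodels.api as sm

    f = frames[(frames["first_sign"] != 0) & (frames["last_sign"] != 0)]

    def fallback(x, y):
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(x, y)[0, 1]
        return slope_cap * (np.sign(c) if np.isfinite(c) and c != 0 else 1.0)

    slopes, capped = [], 0
    for p, grp in f.groupby("participant"):
        x = grp["first_sign"].to_numpy(dtype=float)
        y = (grp["last_sign"].to_numpy() > 0).astype(float)
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            # degenerate input: one sign never occurs for this participant
            slopes.append(0.0)
            capped += 1
            logger.info("participant %s: degenerate sign table; slope set to 0", p)
            continue
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
            slope = float(fit.params[1])
            if not np.isfinite(slope):
                slope = fallback(x, y)
                capped += 1
            elif abs(slope) > slope_cap:
                slope = float(np.clip(slope, -slope_cap, slope_cap))
                capped += 1
                logger.info("participant %s: separated logistic fit capped", p)
        except Exception:
            slope = fallback(x, y)
            capped += 1
            logger.info("participant %s: logistic fit failed; slope capped", p)
        slopes.append(slope)
    slopes = np.asarray(slopes, dtype=float)
    if len(slopes) < 2:
        raise ValueError("first_last_sign_model needs >= 2 participants")
    return {"slopes": slopes, "test": one_sample_t(slopes),
            "n_capped": int(capped)}


def second_frame_repulsive_fraction(frames: pd.DataFrame) -> dict:
    """Among trials that end with an attractive bias, the percentage whose
    second recorded sample already deviates away from the previous stimulus."""
    attr = frames[frames["last_sign"] > 0]
    usable = attr[(attr["n_samples"] >= 2) & attr["second_sign"].notna()
                  & (attr["second_sign"] != 0)]
    skipped = int(len(attr) - len(usable))
    if usable.empty:
        raise ValueError("no attractive-ending trials with a second sample")
    pct = 100.0 * float((usable["second_sign"] < 0).mean())
    return {"percent_repulsive": pct, "n": int(len(usable)),
            "n_skipped": skipped}


def plot_surface(surface: BiasSurface, ax=None):
    """Optional heat-map of a bias surface (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lim = np.nanmax(np.abs(surface.bias))
    im = ax.pcolormesh(surface.time_grid * 1000.0, surface.diss_grid,
                       surface.bias.T, cmap="RdBu_r", vmin=-lim, vmax=lim,
                       shading="auto")
    ax.contour(surface.time_grid * 1000.0, surface.diss_grid,
               surface.significant.T.astype(float), levels=[0.5],
               colors="k", linestyles="--", linewidths=0.8)
    ax.set_xlabel("time to response (ms)")
    ax.set_ylabel("dissimilarity (deg)")
    ax.set_title(f"{surface.condition} ({surface.unit})")
    plt.colorbar(im, ax=ax, label=f"toward-coded bias ({surface.unit})")
    return ax
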