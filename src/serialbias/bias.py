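"""The density-asymmetry serial-bias statistic.

Serial bias is measured as the asymmetry between response errors made toward
versus away from the previous trial's stimulus. Errors are first toward-coded
(positive = toward the previous stimulus), then the asymmetry is the signed
mass difference between the two sides, normalized by the total mass and
scaled to percent:

    asymmetry = 100 * (mass_toward - mass_away) / (mass_toward + mass_away)

With unit weights this is exactly ``100 * (n+ - n-) / (n+ + n-)`` over the
nonzero toward-coded errors: +100% means every error was toward the previous
stimulus, -100% means every error was away. Unlike the mean error, the
statistic is insensitive to error magnitude, so biases at small and large
stimulus dissimilarities are comparable.

A rolling Gaussian kernel over dissimilarity turns the scalar into a
continuous bias curve; an optional kernel-density variant (``method="kde"``)
is available for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import signed_diff, toward_previous_sign

__all__ = [
    "BiasEstimate",
    "BiasCurve",
    "density_asymmetry",
    "rolling_asymmetry",
    "mean_error_bias",
    "add_previous_context",
    "toward_coded_errors",
    "per_subject_bias",
]

logger = logging.getLogger(__name__)


@dataclass
class BiasEstimate:
    """Scalar density-asymmetry estimate (percent, bounded by +-100)."""

    asymmetry: float
    n_toward: float
    n_away: float
    condition: str | None = None
    participant: object = None


@dataclass
class BiasCurve:
    """Density asymmetry as a continuous function of dissimilarity."""

    grid: np.ndarray          # dissimilarity values, degrees in [0, 180]
    asymmetry: np.ndarray     # percent; NaN where unsupported
    effective_n: np.ndarray   # kernel mass per grid point
    supported: np.ndarray     # effective_n >= floor and both sides weighted
    kernel_sd: float


def density_asymmetry(toward_errors, weights=None, method: str = "count",
                      condition=None, participant=None) -> BiasEstimate:
    """Density asymmetry of toward-coded errors, in percent.

    Exact zeros carry no toward/away information and are dropped. With
    ``method="count"`` (default) the densities reduce to (weighted) sign
    counts; ``method="kde"`` integrates a Gaussian KDE of the error
    distribution on each side of zero instead.
    """
    e = np.asarray(toward_errors, dtype=float)
    if weights is None:
        w = np.ones_like(e)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != e.shape:
            raise ValueError("weights must match toward_errors in length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    nz = e != 0.0
    e, w = e[nz], w[nz]
    if e.size == 0 or w.sum() == 0:
        raise ValueError("undefined asymmetry: no nonzero toward-coded errors")

    if method == "count":
        toward = float(w[e > 0].sum())
        away = float(w[e < 0].sum())
    elif method == "kde":
        if e.size < 2 or np.all(e > 0) or np.all(e < 0):
            # KDE needs both sides to place mass; fall back to counts
            toward = float(w[e > 0].sum())
            away = float(w[e < 0].sum())
        else:
            kde = stats.gaussian_kde(e, weights=w)
            toward = float(kde.integrate_box_1d(0.0, np.inf))
            away = float(kde.integrate_box_1d(-np.inf, 0.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    asym = 100.0 * (toward - away) / (toward + away)
    return BiasEstimate(asym, toward, away, condition=condition,
                        participant=participant)


def mean_error_bias(toward_errors) -> float:
    """Arithmetic mean of toward-coded errors, degrees (companion measure to
    the density asymmetry; same sign convention)."""
    e = np.asarray(toward_errors, dtype=float)
    if e.size == 0:
        raise ValueError("mean_error_bias: empty input")
    return float(np.mean(e))


def rolling_asymmetry(toward_errors, dissimilarities, kernel_sd: float = 20.0,
                      grid=None, min_effective_n: float = 5.0,
                      method: str = "count") -> BiasCurve:
    """Density asymmetry as a continuous function of dissimilarity.

    At each grid point ``d`` the asymmetry is computed with Gaussian weights
    ``exp(-(|delta_i| - d)^2 / (2 * kernel_sd^2))``. Points whose kernel mass
    falls below ``min_effective_n`` (or where one side carries no weight at
    all because no errors remain) are flagged unsupported, not errors.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be > 0")
    e = np.asarray(toward_errors, dtype=float)
    d = np.abs(np.asarray(dissimilarities, dtype=float))
    if e.shape != d.shape:
        raise ValueError("toward_errors and dissimilarities must match in length")
    if grid is None:
        grid = np.linspace(0.0, 180.0, 91)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0 or grid.max() > 180:
        raise ValueError("grid must lie within [0, 180]")

    asym = np.full(grid.shape, np.nan)
    eff = np.zeros(grid.shape)
    for i, g in enumerate(grid):
        w = np.exp(-((d - g) ** 2) / (2.0 * kernel_sd ** 2))
        eff[i] = float(w[e != 0].sum())
        if eff[i] >= min_effective_n:
            try:
                asym[i] = density_asymmetry(e, weights=w, method=method).asymmetry
            except ValueError:
                pass  # stays NaN / unsupported
    supported = np.isfinite(asym) & (eff >= min_effective_n)
    return BiasCurve(grid=grid, asymmetry=asym, effective_n=eff,
                     supported=supported, kernel_sd=kernel_sd)


def add_previous_context(trials: pd.DataFrame) -> pd.DataFrame:
    """Pair each trial with the previous trial of the same block.

    Adds ``prev_target``, ``delta_prev`` (signed previous - current target,
    degrees), ``dissimilarity`` (|delta_prev|) and ``valid_prev``. The first
    trial of each block has no valid predecessor; a predecessor flagged as an
    error outlier breaks the chain for the following trial as well.
    """
    df = trials.sort_values(["participant", "condition", "trial_index"],
                            kind="mergesort").copy()
    if "block" not in df.columns:
        df["block"] = 0
    grp = df.groupby(["participant", "condition", "block"], observed=True, sort=False)
    df["prev_target"] = grp["target"].shift(1)
    valid = df["prev_target"].notna()
    if "error_outlier" in df.columns:
        prev_outlier = grp["error_outlier"].shift(1)
        valid &= prev_outlier.ne(True)
    df["delta_prev"] = signed_diff(df["prev_target"].fillna(0.0).to_numpy(),
                                   df["target"].to_numpy())
    df.loc[~valid, "delta_prev"] = np.nan
    df["dissimilarity"] = df["delta_prev"].abs()
    df["valid_prev"] = valid
    return df


def toward_coded_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for bias estimation, with a ``toward_error`` column.

    Requires anisotropy-corrected errors. Excludes outliers, trials without a
    valid predecessor, and trials whose previous stimulus was identical to the
    current one (toward/away undefined at delta = 0).
    """
    if "corrected_error" not in trials.columns:
        raise ValueError("toward_coded_errors: run the anisotropy correction first")
    df = trials if "valid_prev" in trials.columns else add_previous_context(trials)
    ok = (df["valid_prev"]
          & ~df.get("error_outlier", pd.Series(False, index=df.index))
          & df["delta_prev"].ne(0.0) & df["delta_prev"].notna())
    out = df.loc[ok].copy()
    out["toward_error"] = toward_previous_sign(out["corrected_error"].to_numpy(),
                                               out["delta_prev"].to_numpy())
    return out


def per_subject_bias(trials: pd.DataFrame, method: str = "count"):
    """Per participant x condition density asymmetry, plus the
    cross-condition correlation of the per-subject estimates.

    Returns ``(estimates, correlation)`` where ``estimates`` is a tidy frame
    (participant, condition, asymmetry, mean_error, n_toward, n_away, n) and
    ``correlation`` is a dict with Pearson ``r``, ``p`` and ``n`` (NaN with a
    note when fewer than 3 participants have both conditions).
    """
    coded = toward_coded_errors(trials)
    rows = []
    for (p, cond), grp in coded.groupby(["participant", "condition"],
                                        observed=True):
        e = grp["toward_error"].to_numpy()
        try:
            est = density_asymmetry(e, method=method, condition=cond,
                                    participant=p)
        except ValueError:
            logger.warning("participant %s has no usable trials in condition %s;"
                           " excluded", p, cond)
            continue
        rows.append({
            "participant": p, "condition": cond,
            "asymmetry": est.asymmetry, "mean_error": mean_error_bias(e),
            "n_toward": est.n_toward, "n_away": est.n_away, "n": len(e),
        })
    estimates = pd.DataFrame(rows)

    correlation = {"r": float("nan"), "p": float("nan"), "n": 0,
                   "note": "undefined: fewer than 3 participants with both conditions"}
    if not estimates.empty:
        wide = estimates.pivot(index="participant", columns="condition",
                               values="asymmetry").dropna()
        if wide.shape[1] == 2 and len(wide) >= 3:
            r, pval = stats.pearsonr(wide.iloc[:, 0], wide.iloc[:, 1])
            correlation = {"r": float(r), "p": float(pval), "n": len(wide),
                           "note": ""}
        else:
            correlation["n"] = len(wide)
    return estimates, correlation
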