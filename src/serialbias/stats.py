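"""Group-level inference for the direction-report experiment.

One-sample and paired t-tests with effect sizes, Cousineau-Morey
within-subject confidence intervals, Stroop congruency contrasts, condition
contrasts on the per-subject bias estimates, and the RT-vs-dissimilarity
regression (two-stage by default; optional linear mixed model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "PairedResult",
    "RtModelFit",
    "one_sample_t",
    "paired_t",
    "within_subject_ci",
    "stroop_congruency_contrast",
    "condition_bias_contrast",
    "rt_dissimilarity_model",
]

logger = logging.getLogger(__name__)


@dataclass
class TTestResult:
    """One-sample t-test summary."""

    mean: float
    se: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    d: float  # mean / SD
    n: int

    def to_dict(self):
        return {k: float(v) if k != "df" and k != "n" else int(v)
                for k, v in self.__dict__.items()}


@dataclass
class PairedResult:
    """Paired (within-subject) contrast between two conditions."""

    labels: tuple
    mean_a: float
    mean_b: float
    mean_diff: float
    t: float
    df: int
    p: float
    d: float  # mean difference / SD of differences
    ci_low: float
    ci_high: float
    n: int

    def to_dict(self):
        d = dict(self.__dict__)
        d["labels"] = list(self.labels)
        for k in ("mean_a", "mean_b", "mean_diff", "t", "p", "d",
                  "ci_low", "ci_high"):
            d[k] = float(d[k])
        d["df"] = int(d["df"])
        d["n"] = int(d["n"])
        return d


def one_sample_t(values, popmean: float = 0.0, level: float = 0.95) -> TTestResult:
    """One-sample t-test of ``values`` against ``popmean`` with a
    ``level`` confidence interval and Cohen's d."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError("one_sample_t needs at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if se == 0:
        t = 0.0 if mean == popmean else float(np.sign(mean - popmean)) * np.inf
        p = 1.0 if mean == popmean else 0.0
        d = t
    else:
        t = (mean - popmean) / se
        p = 2.0 * sps.t.sf(abs(t), df)
        d = (mean - popmean) / sd
    half = sps.t.ppf(0.5 + level / 2.0, df) * se
    return TTestResult(mean=mean, se=float(se), t=float(t), df=df, p=float(p),
                       ci_low=mean - half, ci_high=mean + half, d=float(d), n=n)


def paired_t(a, b, labels=("a", "b"), level: float = 0.95) -> PairedResult:
    """Paired t-test a vs b (difference a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired_t: unequal lengths")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    res = one_sample_t(a - b, 0.0, level)
    return PairedResult(labels=tuple(labels), mean_a=float(np.mean(a)),
                        mean_b=float(np.mean(b)), mean_diff=res.mean,
                        t=res.t, df=res.df, p=res.p, d=res.d,
                        ci_low=res.ci_low, ci_high=res.ci_high, n=res.n)


def within_subject_ci(matrix, level: float = 0.95) -> pd.DataFrame:
    """Cousineau-Morey within-subject confidence intervals.

    ``matrix`` is a participants x conditions frame (or array). Each row is
    centered on its own mean (removing between-subject variability), the
    per-condition variances of the centered data are rescaled by C/(C-1), and
    CIs are built from the adjusted SEs. With a single condition this falls
    back to the ordinary CI (with a log note).
    """
    m = pd.DataFrame(matrix).dropna()
    n, c = m.shape
    if n < 2:
        raise ValueError("within_subject_ci needs at least 2 complete rows")
    if c == 1:
        logger.info("within_subject_ci: single condition; ordinary CI used")
        adjusted = m.to_numpy(dtype=float)
        scale = 1.0
    else:
        vals = m.to_numpy(dtype=float)
        adjusted = vals - vals.mean(axis=1, keepdims=True) + vals.mean()
        scale = np.sqrt(c / (c - 1.0))
    half = sps.t.ppf(0.5 + level / 2.0, n - 1)
    rows = []
    for j, cond in enumerate(m.columns):
        se = np.std(adjusted[:, j], ddof=1) * scale / np.sqrt(n)
        mean = float(m.iloc[:, j].mean())
        rows.append({"condition": cond, "mean": mean, "se": float(se),
                     "ci_low": mean - half * se, "ci_high": mean + half * se,
                     "n": n})
    return pd.DataFrame(rows)


def stroop_congruency_contrast(trials: pd.DataFrame) -> dict:
    """Congruent vs incongruent Stroop performance, per condition.

    Paired t-tests across participants on mean Stroop RT (seconds) and
    accuracy (percent correct). Practice trials are excluded. In the fixed-key
    condition both contrasts are expected null.
    """
    required = {"stroop_congruent", "stroop_rt", "stroop_correct"}
    if not required.issubset(trials.columns):
        raise ValueError(f"missing Stroop columns: {sorted(required - set(trials.columns))}")
    df = trials
    if "is_practice" in df.columns:
        df = df[~df["is_practice"]]
    out = {}
    for cond, sub in df.groupby("condition", observed=True):
        per = sub.groupby(["participant", "stroop_congruent"], observed=True).agg(
            rt=("stroop_rt", "mean"),
            accuracy=("stroop_correct", lambda x: 100.0 * np.mean(x)),
        ).reset_index()
        res = {}
        for measure in ("rt", "accuracy"):
            wide = per.pivot(index="participant", columns="stroop_congruent",
                             values=measure).dropna()
            if True not in wide.columns or False not in wide.columns or len(wide) < 2:
                raise ValueError(
                    f"condition {cond}: not enough participants with both "
                    f"congruent and incongruent trials")
            res[measure] = paired_t(wide[True].to_numpy(), wide[False].to_numpy(),
                                    labels=("congruent", "incongruent"))
        out[str(cond)] = res
    return out


def condition_bias_contrast(estimates: pd.DataFrame) -> dict:
    """Condition contrast on per-subject density asymmetries.

    Paired t-test between the two conditions, per-condition one-sample tests
    against 0, within-subject CIs, and the cross-condition Pearson
    correlation. Participants missing a condition are dropped with a log note.
    """
    wide = estimates.pivot(index="participant", columns="condition",
                           values="asymmetry")
    dropped = int(wide.isna().any(axis=1).sum())
    if dropped:
        logger.info("condition_bias_contrast: dropped %d unmatched participants",
                    dropped)
    wide = wide.dropna()
    conds = list(wide.columns)
    if len(conds) != 2 or len(wide) < 2:
        raise ValueError("condition_bias_contrast needs two conditions and >= 2 "
                         "matched participants")
    a, b = wide[conds[0]].to_numpy(), wide[conds[1]].to_numpy()
    corr = {"r": float("nan"), "p": float("nan"), "n": len(wide)}
    if len(wide) >= 3:
        r, p = sps.pearsonr(a, b)
        corr = {"r": float(r), "p": float(p), "n": len(wide)}
    return {
        "contrast": paired_t(a, b, labels=tuple(map(str, conds))),
        "per_condition": {str(c): one_sample_t(wide[c].to_numpy()) for c in conds},
        "within_subject_ci": within_subject_ci(wide),
        "correlation": corr,
        "n_dropped": dropped,
    }


@dataclass
class RtModelFit:
    """RT ~ dissimilarity x condition fit summary.

    ``slope`` is ms per degree of dissimilarity; ``condition_offset`` is the
    ms shift of the second condition; ``interaction`` the slope change there.
    """

    method: str
    slope: TTestResult
    condition_offset: TTestResult
    interaction: TTestResult
    intercept: TTestResult
    per_participant: pd.DataFrame
    n_excluded: int

    def to_dict(self):
        return {
            "method": self.method,
            "n_excluded": self.n_excluded,
            "slope_ms_per_deg": self.slope.to_dict(),
            "condition_offset_ms": self.condition_offset.to_dict(),
            "interaction_ms_per_deg": self.interaction.to_dict(),
            "intercept_ms": self.intercept.to_dict(),
        }


def rt_dissimilarity_model(trials: pd.DataFrame, method: str = "two_stage",
                           min_trials: int = 10, rt_ceiling: float = 10.0) -> RtModelFit:
    """How report RT depends on current-previous dissimilarity and condition.

    Default is a two-stage fit: per-participant OLS of RT (ms) on
    dissimilarity (deg), a condition indicator and their interaction, then
    one-sample t-tests of the coefficients across participants. With
    ``method="mixed"`` a linear mixed model (random intercept + dissimilarity
    slope per participant) estimates the same fixed effects.

    Trials need a valid predecessor (dissimilarity defined) and a positive
    sub-ceiling RT; participants with fewer than ``min_trials`` valid trials
    are excluded with a log entry.
    """
    from .bias import add_previous_context

    df = trials if "dissimilarity" in trials.columns else add_previous_context(trials)
    conds = sorted(df["condition"].unique().tolist())
    if len(conds) != 2:
        raise ValueError("rt_dissimilarity_model expects exactly two conditions")
    ok = (df["dissimilarity"].notna() & (df["report_rt"] > 0)
          & (df["report_rt"] < rt_ceiling))
    df = df.loc[ok, ["participant", "condition", "dissimilarity", "report_rt"]].copy()
    df["rt_ms"] = df["report_rt"] * 1000.0
    df["cond2"] = (df["condition"] == conds[1]).astype(float)

    rows, excluded = [], 0
    for p, grp in df.groupby("participant"):
        if len(grp) < min_trials or grp["cond2"].nunique() < 2:
            excluded += 1
            logger.info("rt model: participant %s excluded (%d valid trials)",
                        p, len(grp))
            continue
        X = np.column_stack([
            np.ones(len(grp)),
            grp["dissimilarity"].to_numpy(),
            grp["cond2"].to_numpy(),
            grp["dissimilarity"].to_numpy() * grp["cond2"].to_numpy(),
        ])
        beta, *_ = np.linalg.lstsq(X, grp["rt_ms"].to_numpy(), rcond=None)
        rows.append({"participant": p, "intercept": beta[0], "slope": beta[1],
                     "condition_offset": beta[2], "interaction": beta[3],
                     "n": len(grp)})
    per = pd.DataFrame(rows)
    if len(per) < 2:
        raise ValueError("rt_dissimilarity_model: fewer than 2 usable participants")

    if method == "two_stage":
        fit = RtModelFit(
            method="two_stage",
            slope=one_sample_t(per["slope"]),
            condition_offset=one_sample_t(per["condition_offset"]),
            interaction=one_sample_t(per["interaction"]),
            intercept=one_sample_t(per["intercept"]),
            per_participant=per,
            n_excluded=excluded,
        )
    elif method == "mixed":
        import statsmodels.formula.api as smf

        keep = df[df["participant"].isin(per["participant"])]
        md = smf.mixedlm("rt_ms ~ dissimilarity * cond2", keep,
                         groups=keep["participant"],
                         re_formula="~dissimilarity")
        mfit = md.fit(reml=True, method="lbfgs")

        def as_result(name):
            est = float(mfit.params[name])
            se = float(mfit.bse[name])
            n = len(per)
            t = est / se if se > 0 else np.inf
            dfree = n - 1
            p = 2.0 * sps.t.sf(abs(t), dfree)
            half = sps.t.ppf(0.975, dfree) * se
            return TTestResult(mean=est, se=se, t=float(t), df=dfree,
                               p=float(p), ci_low=est - half, ci_high=est + half,
                               d=float("nan"), n=n)

        fit = RtModelFit(
            method="mixed",
            slope=as_result("dissimilarity"),
            condition_offset=as_result("cond2"),
            interaction=as_result("dissimilarity:cond2"),
            intercept=as_result("Intercept"),
            per_participant=per,
            n_excluded=excluded,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return fit
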