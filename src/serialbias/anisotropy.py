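"""Removal of cardinal/oblique anisotropies from circular response errors.

Direction reports are systematically attracted to or repelled from the
cardinal directions (0/90/180/270 deg), and their precision varies with
distance to the nearest cardinal (the oblique effect). Both distort
serial-bias estimates, so they are removed per participant before any
bias statistic is computed.

Procedure
---------
For each participant, trials are grouped into four 90-degree bins centered
either on the cardinals or on the obliques. Repulsion from cardinals puts a
discontinuity *at* the cardinals, which oblique-centered bins push to their
edges where a polynomial can cope; attraction is smooth at the cardinals and
is best captured by cardinal-centered bins. Within each bin a fourth-degree
polynomial of the signed distance to the bin center predicts the mean error,
and a quadratic model of the distance to the nearest cardinal predicts the
residual SD. Trials outside +-3 x local SD are excluded from the fit and
added back afterward. The scheme whose polynomials fit better (total Gaussian
log-likelihood under the heteroscedastic SD model) is kept; its predicted
mean error is subtracted from every response, and responses whose corrected
error exceeds +-3 x predicted local SD are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import stats

from .circular import wrap_signed, distance_to_nearest_cardinal

__all__ = [
    "BinScheme",
    "AnisotropyModel",
    "AnisotropyError",
    "cardinal_scheme",
    "oblique_scheme",
    "fit_anisotropy",
    "select_scheme",
    "apply_correction",
    "correct_trials",
]

POLY_DEGREE = 4
SD_POLY_DEGREE = 2
SD_FLOOR = 0.5  # degrees; keeps the predicted SD positive everywhere


class AnisotropyError(ValueError):
    """Raised when an anisotropy model cannot be fitted."""


@dataclass(frozen=True)
class BinScheme:
    """Four evenly spaced direction bins of 90 degrees each."""

    name: str
    centers: tuple

    def assign(self, targets):
        """Return ``(bin_index, signed_distance_to_center)`` per trial."""
        t = np.asarray(targets, dtype=float)
        d = wrap_signed(t[:, None] - np.asarray(self.centers, dtype=float)[None, :])
        idx = np.argmin(np.abs(d), axis=1)
        return idx, d[np.arange(len(t)), idx]


def cardinal_scheme() -> BinScheme:
    return BinScheme("cardinal", (0.0, 90.0, 180.0, 270.0))


def oblique_scheme() -> BinScheme:
    return BinScheme("oblique", (45.0, 135.0, 225.0, 315.0))


@dataclass
class AnisotropyModel:
    """Fitted per-participant anisotropy model."""

    scheme: BinScheme
    polynomials: list  # one numpy Polynomial per bin
    sd_polynomial: Polynomial  # SD vs |distance to nearest cardinal|
    sd_floor: float
    log_likelihood: float
    n_trials: int
    n_excluded_from_fit: int

    def predict_mean(self, targets):
        """Predicted anisotropic mean error at each target direction."""
        t = np.atleast_1d(np.asarray(targets, dtype=float))
        idx, d = self.scheme.assign(t)
        out = np.empty_like(d)
        for b, poly in enumerate(self.polynomials):
            sel = idx == b
            if sel.any():
                out[sel] = poly(d[sel])
        return out

    def predict_sd(self, targets):
        """Predicted local response SD (always >= ``sd_floor``)."""
        t = np.atleast_1d(np.asarray(targets, dtype=float))
        dc = np.abs(distance_to_nearest_cardinal(t))
        return np.maximum(self.sd_polynomial(dc), self.sd_floor)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.name,
            "polynomial_coefficients": [
                list(map(float, p.convert().coef)) for p in self.polynomials
            ],
            "sd_coefficients": list(map(float, self.sd_polynomial.convert().coef)),
            "sd_floor": self.sd_floor,
            "log_likelihood": float(self.log_likelihood),
            "n_trials": int(self.n_trials),
            "n_excluded_from_fit": int(self.n_excluded_from_fit),
        }


def _fit_bin_polys(idx, d, errors, scheme, keep, min_points=POLY_DEGREE + 2):
    polys = []
    for b, center in enumerate(scheme.centers):
        sel = (idx == b) & keep
        if sel.sum() < min_points:
            raise AnisotropyError(
                f"singular fit: bin centered at {center:g} deg retains "
                f"{int(sel.sum())} trials (< {min_points})")
        polys.append(Polynomial.fit(d[sel], errors[sel], POLY_DEGREE))
    return polys


def _fit_sd_model(dc, resid, keep, sd_floor):
    """Quadratic model of residual SD vs distance-to-nearest-cardinal,
    fitted to SDs of 5-degree distance bins."""
    edges = np.linspace(0.0, 45.0, 10)
    mids, sds, ns = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = keep & (dc >= lo) & (dc < hi if hi < 45 else dc <= hi)
        if sel.sum() >= 5:
            mids.append((lo + hi) / 2.0)
            sds.append(np.std(resid[sel], ddof=1))
            ns.append(sel.sum())
    if len(mids) <= SD_POLY_DEGREE:
        raise AnisotropyError("singular fit: too few distance bins for the SD model")
    poly = Polynomial.fit(np.asarray(mids), np.asarray(sds), SD_POLY_DEGREE,
                          w=np.sqrt(np.asarray(ns, dtype=float)))
    return poly


def fit_anisotropy(targets, errors, scheme: BinScheme, min_per_bin: int = 25,
                   sd_floor: float = SD_FLOOR) -> AnisotropyModel:
    """Fit the per-bin quartic mean-error model and the heteroscedastic SD
    model for one participant.

    Trials whose first-pass residual exceeds 3 x the local SD are excluded
    from a second fitting pass and added back afterward; the returned
    log-likelihood is evaluated on all trials.
    """
    t = np.asarray(targets, dtype=float)
    e = np.asarray(errors, dtype=float)
    if t.shape != e.shape:
        raise ValueError("targets and errors must have the same length")
    idx, d = scheme.assign(t)
    counts = np.bincount(idx, minlength=4)
    for b, center in enumerate(scheme.centers):
        if counts[b] == 0:
            raise AnisotropyError(f"bin centered at {center:g} deg is empty")
        if counts[b] < min_per_bin:
            raise AnisotropyError(
                f"bin centered at {center:g} deg has {counts[b]} trials "
                f"(< min_per_bin={min_per_bin})")

    keep = np.ones(len(t), dtype=bool)
    dc = np.abs(distance_to_nearest_cardinal(t))

    # pass 1: fit on everything, estimate the SD profile
    polys = _fit_bin_polys(idx, d, e, scheme, keep)
    resid = e - AnisotropyModel(scheme, polys, Polynomial([1.0]), sd_floor,
                                0.0, len(t), 0).predict_mean(t)
    sd_poly = _fit_sd_model(dc, resid, keep, sd_floor)
    sd = np.maximum(sd_poly(dc), sd_floor)

    # pass 2: refit without the +-3 SD outliers, then add them back
    keep = np.abs(resid) <= 3.0 * sd
    n_excluded = int((~keep).sum())
    polys = _fit_bin_polys(idx, d, e, scheme, keep)
    model = AnisotropyModel(scheme, polys, sd_poly, sd_floor, 0.0, len(t),
                            n_excluded)
    resid = e - model.predict_mean(t)
    sd_poly = _fit_sd_model(dc, resid, keep, sd_floor)
    model.sd_polynomial = sd_poly
    sd = model.predict_sd(t)
    model.log_likelihood = float(np.sum(stats.norm.logpdf(resid, 0.0, sd)))
    return model


def select_scheme(targets, errors, min_per_bin: int = 25,
                  sd_floor: float = SD_FLOOR) -> AnisotropyModel:
    """Fit cardinal- and oblique-centered schemes and keep the better one.

    Ties (equal log-likelihood) break deterministically to the
    cardinal-centered scheme.
    """
    card = fit_anisotropy(targets, errors, cardinal_scheme(), min_per_bin, sd_floor)
    obli = fit_anisotropy(targets, errors, oblique_scheme(), min_per_bin, sd_floor)
    return _choose(card, obli)


def _choose(cardinal_model: AnisotropyModel,
            oblique_model: AnisotropyModel) -> AnisotropyModel:
    if oblique_model.log_likelihood > cardinal_model.log_likelihood:
        return oblique_model
    return cardinal_model


def apply_correction(model: AnisotropyModel, targets, errors) -> pd.DataFrame:
    """Subtract the predicted anisotropy and flag outliers.

    Returns a frame with columns ``raw_error``, ``predicted_error``,
    ``corrected_error``, ``local_sd`` and ``outlier`` (corrected error beyond
    +-3 x predicted local SD). Never drops trials — flags are sticky
    downstream.
    """
    t = np.asarray(targets, dtype=float)
    e = np.asarray(errors, dtype=float)
    pred = model.predict_mean(t)
    corrected = wrap_signed(e - pred)
    sd = model.predict_sd(t)
    return pd.DataFrame({
        "raw_error": e,
        "predicted_error": pred,
        "corrected_error": corrected,
        "local_sd": sd,
        "outlier": np.abs(corrected) > 3.0 * sd,
    })


def correct_trials(trials: pd.DataFrame, min_per_bin: int = 25,
                   sd_floor: float = SD_FLOOR):
    """Per-participant anisotropy correction of a trial table.

    Expects ``participant``, ``target`` and either ``error`` or
    ``report`` columns. Returns ``(corrected_table, models)`` where the table
    gains ``predicted_error``, ``corrected_error``, ``error_outlier`` and
    ``anisotropy_scheme`` columns and ``models`` maps participant ->
    :class:`AnisotropyModel`. Fitting always pools a participant's two
    conditions (the anisotropy is a property of the observer, not the task).
    """
    df = trials.copy()
    if "error" not in df.columns:
        df["error"] = wrap_signed(df["report"].to_numpy() - df["target"].to_numpy())
    df["predicted_error"] = np.nan
    df["corrected_error"] = np.nan
    df["error_outlier"] = False
    df["anisotropy_scheme"] = ""
    models = {}
    for p, grp in df.groupby("participant", sort=True):
        model = select_scheme(grp["target"].to_numpy(), grp["error"].to_numpy(),
                              min_per_bin=min_per_bin, sd_floor=sd_floor)
        res = apply_correction(model, grp["target"].to_numpy(),
                               grp["error"].to_numpy())
        df.loc[grp.index, "predicted_error"] = res["predicted_error"].to_numpy()
        df.loc[grp.index, "corrected_error"] = res["corrected_error"].to_numpy()
        df.loc[grp.index, "error_outlier"] = res["outlier"].to_numpy()
        df.loc[grp.index, "anisotropy_scheme"] = model.scheme.name
        models[p] = model
    return df, models
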