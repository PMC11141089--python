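"""Dose–response layer: melatonin AUC and closed-form regression.

The study's figure-level statistics are ordinary least squares of an
outcome (pupil median, melatonin AUC) against a log10-transformed light
dose, reported with the Pearson correlation.  Both are computed in closed
form here — slope = Sxy/Sxx, r = Sxy/√(Sxx·Syy) — so the package's
regression surface carries no fitting-library behavior, and the
corneal-vs-retinal predictor comparison is a simple paired report of the
two fits and the difference of |r|.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSystemError, InsufficientDataError, ValidationError
from .retinal import log10_dose

__all__ = [
    "MelatoninSeries",
    "DoseResponseFit",
    "melatonin_auc",
    "fit_dose_response",
    "compare_predictors",
]


@dataclass(frozen=True)
class MelatoninSeries:
    """Half-hourly salivary melatonin for one subject/session.

    ``times_h`` are hours relative to habitual bedtime (strictly
    increasing); ``conc_pg_ml`` are concentrations >= 0.
    """

    times_h: np.ndarray
    conc_pg_ml: np.ndarray
    subject: str = ""
    session: str = ""

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_pg_ml, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "conc_pg_ml", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValidationError("times and concentrations must match 1-D")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS of an outcome against (log10) dose, with Pearson correlation."""

    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    residual_sd: float
    predictor: str = ""


def melatonin_auc(series: MelatoninSeries, window: tuple) -> float:
    """Trapezoidal area under the melatonin curve inside ``window``, pg/ml·h.

    Additive over adjacent windows that share a sampled endpoint."""
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValidationError("window end must exceed its start")
    mask = (series.times_h >= t0) & (series.times_h <= t1)
    t = series.times_h[mask]
    c = series.conc_pg_ml[mask]
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 samples in window [{t0}, {t1}], got {t.size}"
        )
    return float(np.trapezoid(c, t))


def fit_dose_response(dose, outcome, log_transform: bool = True,
                      predictor: str = "") -> DoseResponseFit:
    """Closed-form OLS slope/intercept and Pearson r of outcome vs dose.

    With ``log_transform`` the predictor is log10(dose); nonpositive doses
    are then a hard error.  Requires n >= 3 and nonzero predictor variance.
    """
    x = np.asarray(dose, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("dose and outcome must be matching 1-D arrays")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 points for a fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("dose and outcome must be finite")
    if log_transform:
        x = log10_dose(x)
    xm, ym = x - x.mean(), y - y.mean()
    sxx = float(np.dot(xm, xm))
    syy = float(np.dot(ym, ym))
    sxy = float(np.dot(xm, ym))
    if sxx == 0.0:
        raise DegenerateSystemError("predictor has zero variance")
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else float("nan")
    resid = y - (intercept + slope * x)
    dof = x.size - 2
    residual_sd = float(np.sqrt(np.dot(resid, resid) / dof)) if dof else 0.0
    return DoseResponseFit(
        slope=float(slope), intercept=intercept, r=float(r),
        r2=float(r * r) if np.isfinite(r) else float("nan"),
        n=int(x.size), residual_sd=residual_sd, predictor=predictor,
    )


def compare_predictors(auc, medi_lx, mel_td) -> dict:
    """Fit melatonin AUC against log10 mEDI and log10 melanopic trolands.

    All three arrays are aligned by subject-session.  Returns both fits
    plus ``delta_abs_r`` = |r(mel_td)| − |r(mEDI)| (positive when the
    retinal dose predicts better); purely descriptive, no inferential
    test."""
    auc = np.asarray(auc, dtype=float)
    fit_corneal = fit_dose_response(medi_lx, auc, predictor="mEDI")
    fit_retinal = fit_dose_response(mel_td, auc, predictor="melanopic_Td")
    return {
        "mEDI": fit_corneal,
        "melanopic_Td": fit_retinal,
        "delta_abs_r": abs(fit_retinal.r) - abs(fit_corneal.r),
    }
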