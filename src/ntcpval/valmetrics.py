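"""External-validation metrics: calibration, discrimination, goodness of fit.

Weak calibration is summarized by the intercept and slope of a logistic
regression of the outcome on the model's linear predictor; (0, 1) is
perfect. Calibration-in-the-large compares mean predicted risk with the
observed event rate and, in its offset form, re-estimates only the
intercept with the linear predictor held fixed. Discrimination is the
concordance (AUC); overall accuracy the Brier score; and goodness of fit
the Hosmer-Lemeshow chi-square over equal-count risk bins — the same bins
drawn in the calibration curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit
from sklearn.metrics import roc_auc_score

from .errors import DataError, FittingError


def _as_arrays(p, y):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.ndim != 1 or p.size == 0:
        raise DataError("p and y must be equal-length non-empty 1-d arrays")
    return p, y


def log_likelihood(p, y) -> float:
    """Bernoulli log-likelihood sum(y ln p + (1-y) ln(1-p))."""
    p, y = _as_arrays(p, y)
    bad = ((p <= 0) & (y == 1)) | ((p >= 1) & (y == 0))
    if bad.any():
        raise DataError("probability of exactly 0/1 contradicting the outcome")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y == 1, np.log(p), np.log1p(-p))
    return float(np.sum(terms))


def calibration_in_the_large(p, y) -> tuple[float, float, float]:
    """(mean predicted, observed rate, offset-form intercept).

    The intercept is the MLE of ``logit pi = a + lp`` with ``lp = logit(p)``
    held fixed — the amount by which predictions are off on the logit scale
    with the dose response taken as given.
    """
    p, y = _as_arrays(p, y)
    mean_pred = float(np.mean(p))
    observed = float(np.mean(y))
    if len(np.unique(y)) < 2:
        raise FittingError("constant outcome: offset intercept is not estimable")
    lp = logit(np.clip(p, 1e-12, 1 - 1e-12))
    res = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp).fit(
        maxiter=100, tol=1e-10
    )
    return mean_pred, observed, float(res.params[0])


def calibration_slope_intercept(lp, y) -> tuple[float, float]:
    """MLE (a, b) of ``logit pi = a + b*lp``; the joint weak-calibration fit."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise DataError("linear predictor must be finite")
    if len(np.unique(y)) < 2:
        raise FittingError("both outcome classes must be present")
    try:
        res = sm.GLM(
            y, np.column_stack([np.ones(len(y)), lp]), family=sm.families.Binomial()
        ).fit(maxiter=100, tol=1e-10)
    except Exception as exc:
        raise FittingError(f"calibration fit failed: {exc}") from exc
    a, b = res.params
    if not np.isfinite(a) or not np.isfinite(b) or abs(a) > 50 or abs(b) > 50:
        raise FittingError("calibration fit diverged (separation suspected)")
    return float(a), float(b)


def calibration_curve(p, y, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count risk bins of sorted predictions.

    Remainder observations are spread over the lowest bins. When tied
    predictions straddle a bin boundary the two bins are merged (with a
    warning) so that equal predictions always share a bin. Columns:
    ``n, mean_predicted, observed``, ascending in predicted risk.
    """
    p, y = _as_arrays(p, y)
    n = p.size
    if n < n_bins:
        raise DataError(f"need at least {n_bins} observations for {n_bins} bins")
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    edges = np.cumsum([0] + sizes)
    slices = [(edges[i], edges[i + 1]) for i in range(n_bins)]
    merged: list[tuple[int, int]] = []
    for lo, hi in slices:
        if merged and ps[lo] == ps[lo - 1]:
            warnings.warn("tied predictions straddle a bin boundary; bins merged")
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    rows = [
        {
            "n": hi - lo,
            "mean_predicted": float(np.mean(ps[lo:hi])),
            "observed": float(np.mean(ys[lo:hi])),
        }
        for lo, hi in merged
    ]
    return pd.DataFrame(rows)


def hosmer_lemeshow(p, y, g: int = 10, df: int | None = None) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi-square over g equal-count bins.

    statistic = sum_g (O_g - E_g)^2 / (n_g pbar_g (1 - pbar_g)) with
    E_g = n_g * pbar_g. ``df`` defaults to g_effective - 2 (the development
    convention); pass ``df=g`` for a fully external validation in which no
    parameter was estimated from the data. Bins whose mean prediction is
    exactly 0 or 1 are merged with their neighbor.
    """
    curve = calibration_curve(p, y, n_bins=g)
    rows = curve.to_dict("records")
    i = 0
    while i < len(rows):
        if rows[i]["mean_predicted"] in (0.0, 1.0) and len(rows) > 1:
            warnings.warn("bin with degenerate mean prediction merged with neighbor")
            j = i + 1 if i + 1 < len(rows) else i - 1
            a, b = rows[min(i, j)], rows[max(i, j)]
            ntot = a["n"] + b["n"]
            merged = {
                "n": ntot,
                "mean_predicted": (a["n"] * a["mean_predicted"] + b["n"] * b["mean_predicted"]) / ntot,
                "observed": (a["n"] * a["observed"] + b["n"] * b["observed"]) / ntot,
            }
            rows[min(i, j) : max(i, j) + 1] = [merged]
        else:
            i += 1
    stat = 0.0
    for r in rows:
        pbar, obs, ng = r["mean_predicted"], r["observed"], r["n"]
        stat += (ng * obs - ng * pbar) ** 2 / (ng * pbar * (1 - pbar))
    g_eff = len(rows)
    dof = df if df is not None else max(g_eff - 2, 1)
    return float(stat), int(dof), float(stats.chi2.sf(stat, dof))


def brier(p, y) -> float:
    """Mean squared error of probabilistic predictions."""
    p, y = _as_arrays(p, y)
    return float(np.mean((p - y) ** 2))


def auc(p, y) -> float:
    """Concordance: probability a random event outranks a random non-event (midrank ties)."""
    p, y = _as_arrays(p, y)
    if len(np.unique(y)) < 2:
        raise DataError("AUC undefined with a single outcome class")
    return float(roc_auc_score(y, p))


@dataclass
class ValidationReport:
    """The full metric bundle for one model on one cohort."""

    n: int
    n_events: int
    mean_predicted: float
    observed_rate: float
    citl_intercept: float
    calibration_intercept: float
    calibration_slope: float
    log_likelihood: float
    auc: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    brier: float
    calibration_curve: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def validate_predictions(
    lp, y, n_bins: int = 10, hl_df: int | None = None
) -> ValidationReport:
    """Compute the whole report from linear predictors and binary outcomes."""
    from scipy.special import expit

    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    p = expit(lp)
    mean_pred, observed, citl = calibration_in_the_large(p, y)
    a, b = calibration_slope_intercept(lp, y)
    stat, dof, hl_p = hosmer_lemeshow(p, y, g=n_bins, df=hl_df)
    curve = calibration_curve(p, y, n_bins=n_bins)
    return ValidationReport(
        n=int(y.size),
        n_events=int(y.sum()),
        mean_predicted=mean_pred,
        observed_rate=observed,
        citl_intercept=citl,
        calibration_intercept=a,
        calibration_slope=b,
        log_likelihood=log_likelihood(p, y),
        auc=auc(p, y),
        hl_statistic=stat,
        hl_df=dof,
        hl_p=hl_p,
        brier=brier(p, y),
        calibration_curve=curve.to_dict("records"),
    )
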