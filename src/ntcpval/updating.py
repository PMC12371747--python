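"""Closed testing procedure for model updating.

Four nested candidates are fit on the validation data: the original model
M0 (no free parameters), the intercept-updated model M1 (1), the
recalibrated model M2 (2: intercept and a common slope on the linear
predictor), and the revised model M3 (3: intercept and both dose
coefficients; more when baseline effects are refit). The closed-testing
cascade tests the largest model against each nested candidate with
likelihood-ratio chi-square tests and accepts the simplest candidate that
the data do not reject:

    M3 vs M0 not significant -> keep the original model;
    else M3 vs M1 not significant -> intercept update;
    else M3 vs M2 not significant -> recalibration;
    else -> revision.

This controls the overall type-I error of unnecessary updating at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ntcp, valmetrics
from .errors import FittingError
from .ntcp import FeatureVector, NTCPModel

LEVELS = ("original", "intercept", "recalibration", "revision")


@dataclass
class UpdateDecision:
    chosen_level: str
    log_likelihoods: dict[str, float]
    lr_statistics: dict[str, tuple[float, int, float]]
    alpha: float
    updated_model: NTCPModel

    def to_dict(self) -> dict:
        return {
            "chosen_level": self.chosen_level,
            "log_likelihoods": dict(self.log_likelihoods),
            "lr_statistics": {
                k: {"statistic": s, "df": d, "p": p}
                for k, (s, d, p) in self.lr_statistics.items()
            },
            "alpha": self.alpha,
            "updated_model": self.updated_model.to_dict(),
        }


def closed_test(
    model: NTCPModel,
    features: list[FeatureVector],
    y,
    alpha: float = 0.05,
    refit_baseline: bool = False,
) -> UpdateDecision:
    """Run the closed testing procedure and return the selected update."""
    from scipy import stats
    from scipy.special import expit

    y = np.asarray(y, dtype=float)
    lp = ntcp.linear_predictors(model, features)

    candidates: dict[str, NTCPModel] = {"original": model}
    for level in ("intercept", "recalibration", "revision"):
        try:
            candidates[level] = ntcp.update_model(
                model, lp, y, level, features=features, refit_baseline=refit_baseline
            )
        except FittingError as exc:
            raise FittingError(f"fit failed at update level '{level}': {exc}") from exc

    ll = {
        level: valmetrics.log_likelihood(ntcp.predict_many(m, features), y)
        for level, m in candidates.items()
    }
    # free-parameter counts of the nested hierarchy
    n_free = {"original": 0, "intercept": 1, "recalibration": 2, "revision": 3}
    cats = {
        "none" if f.baseline_category == "missing" else f.baseline_category
        for f in features
    }
    scores = {ntcp.baseline_score(model, c) for c in cats}
    if refit_baseline and len(cats) > 1:
        n_free["revision"] += len(cats - {"none"})
    elif len(scores) > 1:
        n_free["revision"] += 1  # free coefficient on the baseline score

    # numerical tolerance on the nesting invariant
    tol = 1e-6 * max(1.0, abs(ll["original"]))
    assert ll["original"] <= ll["intercept"] + tol
    assert ll["intercept"] <= ll["recalibration"] + tol
    assert ll["recalibration"] <= ll["revision"] + tol

    def lr(simple: str) -> tuple[float, int, float]:
        stat = max(2.0 * (ll["revision"] - ll[simple]), 0.0)
        df = n_free["revision"] - n_free[simple]
        return stat, df, float(stats.chi2.sf(stat, df))

    lr_stats = {f"revision_vs_{s}": lr(s) for s in ("original", "intercept", "recalibration")}

    chosen = "revision"
    for simple in ("original", "intercept", "recalibration"):
        if lr_stats[f"revision_vs_{simple}"][2] >= alpha:
            chosen = simple
            break

    return UpdateDecision(
        chosen_level=chosen,
        log_likelihoods=ll,
        lr_statistics=lr_stats,
        alpha=alpha,
        updated_model=candidates[chosen],
    )
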