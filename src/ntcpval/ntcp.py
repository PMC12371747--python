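"""The xerostomia NTCP model: prediction and model updating.

The reference model is a logistic regression for grade >= 2 xerostomia at
6 months after head-and-neck radiotherapy,

    NTCP = 1 / (1 + exp(-S)),
    S = b0 + b_par * T(Dmean_ipsi_parotid + Dmean_contra_parotid)
           + b_smg * T(Dmean_SMG) + baseline_score,

with mean gland doses in Gy, an additive score for pre-treatment xerostomia
severity (0 none / 0.459 mild / 1.207 moderate-severe), and an optional dose
transform T (identity as printed, or square root as in the model's
ancestors). Model updating follows the standard hierarchy: intercept-only
update (calibration-in-the-large), recalibration (intercept plus a common
slope on the linear predictor), and revision (full re-estimation of the
dose coefficients).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from . import dosimetry
from .errors import ConfigError, DataError, FittingError
from .registry import PatientRecord

DOSE_TRANSFORMS = ("identity", "sqrt")
UPDATE_LEVELS = ("intercept", "recalibration", "revision")


@dataclass
class NTCPModel:
    intercept: float
    coef_parotid: float
    coef_smg: float
    baseline_scores: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "mild": 0.459, "moderate_severe": 1.207}
    )
    dose_transform: str = "identity"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.dose_transform not in DOSE_TRANSFORMS:
            raise ConfigError(f"unknown dose transform {self.dose_transform!r}")
        if abs(self.baseline_scores.get("none", 0.0)) > 1e-12:
            raise ConfigError("baseline score for 'none' must be 0")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_parotid": self.coef_parotid,
            "coef_smg": self.coef_smg,
            "baseline_scores": dict(self.baseline_scores),
            "dose_transform": self.dose_transform,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NTCPModel":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NTCPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_builtin_model(name: str = "lipp") -> NTCPModel:
    """Load a model shipped with the package: ``lipp`` or ``lipp_recalibrated``."""
    ref = resources.files("ntcpval") / "models" / f"{name}.json"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigError(f"no builtin model named {name!r}")
    return NTCPModel.from_dict(json.loads(text))


@dataclass(frozen=True)
class FeatureVector:
    """Aggregated dose features plus the baseline category for one patient."""

    parotid_sum_dose: float
    smg_dose: float
    baseline_category: str = "none"

    def __post_init__(self) -> None:
        if self.parotid_sum_dose < 0 or self.smg_dose < 0:
            raise DataError("dose features must be >= 0")


def baseline_score(model: NTCPModel, category: str) -> float:
    """Additive score for a baseline xerostomia category."""
    if category == "missing":
        category = "none"
    try:
        return model.baseline_scores[category]
    except KeyError:
        raise DataError(f"unknown baseline category {category!r}")


def _transform(x: np.ndarray | float, name: str) -> np.ndarray | float:
    return np.sqrt(x) if name == "sqrt" else x


def linear_predictor(model: NTCPModel, features: FeatureVector) -> float:
    """S = intercept + b_par*T(parotid sum) + b_smg*T(SMG) + baseline score."""
    t = model.dose_transform
    return float(
        model.intercept
        + model.coef_parotid * _transform(features.parotid_sum_dose, t)
        + model.coef_smg * _transform(features.smg_dose, t)
        + baseline_score(model, features.baseline_category)
    )


def predict(model: NTCPModel, features: FeatureVector) -> float:
    """NTCP = inverse logit of the linear predictor; strictly inside (0, 1)."""
    return float(expit(linear_predictor(model, features)))


def linear_predictors(model: NTCPModel, features: list[FeatureVector]) -> np.ndarray:
    return np.array([linear_predictor(model, f) for f in features])


def predict_many(model: NTCPModel, features: list[FeatureVector]) -> np.ndarray:
    return expit(linear_predictors(model, features))


# ---------------------------------------------------------------------------
# Featurization from registry records

def featurize(
    record: PatientRecord,
    dose_representation: str = "eqd2",
    smg_combination: str = "combined",
    alpha_beta: float = 3.0,
    equal_volume_fallback: bool = True,
) -> FeatureVector:
    """Build the model's feature vector from one registry record.

    Doses come from the record's DVH file when present, otherwise from the
    stored per-gland mean doses. With ``dose_representation='eqd2'`` DVHs are
    converted bin by bin; stored summary doses are converted by applying the
    LQ map to the mean itself (exact only for a uniform dose, noted in the
    run log). ``smg_combination`` controls how the two submandibular glands
    enter the single SMG term: volume-weighted ``combined`` (equal weights
    when volumes are absent and the fallback is allowed), plain ``mean``,
    or ``sum``.
    """
    if dose_representation not in ("eqd2", "physical"):
        raise ConfigError(f"unknown dose representation {dose_representation!r}")
    if smg_combination not in ("combined", "mean", "sum"):
        raise ConfigError(f"unknown smg combination {smg_combination!r}")
    scheme = dosimetry.FractionationScheme(
        prescribed_dose=record.prescribed_dose,
        n_fractions=record.n_fractions,
        alpha_beta=alpha_beta,
    )

    if record.dvh_file:
        dvhs = dosimetry.read_dvh_file(record.dvh_file)
        missing = set(dosimetry.STRUCTURE_LABELS) - set(dvhs)
        if missing:
            raise DataError(f"record {record.patient_id}: DVH file lacks {sorted(missing)}")
        if dose_representation == "eqd2":
            dvhs = {k: dosimetry.eqd2_transform(v, scheme) for k, v in dvhs.items()}
        parotid = dosimetry.mean_dose(dvhs["parotid_ipsi"]) + dosimetry.mean_dose(
            dvhs["parotid_contra"]
        )
        smg_pair = [dvhs["smg_ipsi"], dvhs["smg_contra"]]
        if smg_combination == "sum":
            smg = sum(dosimetry.mean_dose(d) for d in smg_pair)
        elif smg_combination == "mean":
            smg = float(np.mean([dosimetry.mean_dose(d) for d in smg_pair]))
        else:
            smg = dosimetry.combined_mean_dose(smg_pair, equal_volume_fallback)
    else:
        needed = set(dosimetry.STRUCTURE_LABELS) - set(record.gland_mean_doses)
        if needed:
            raise DataError(
                f"record {record.patient_id}: no DVH file and missing mean doses {sorted(needed)}"
            )
        doses = dict(record.gland_mean_doses)
        if dose_representation == "eqd2":
            doses = {k: dosimetry.eqd2_bin(v, scheme) for k, v in doses.items()}
        parotid = doses["parotid_ipsi"] + doses["parotid_contra"]
        pair = [doses["smg_ipsi"], doses["smg_contra"]]
        if smg_combination == "sum":
            smg = float(sum(pair))
        else:
            # combined without volumes degenerates to the equal-weight mean
            if smg_combination == "combined" and not equal_volume_fallback:
                raise ConfigError(
                    f"record {record.patient_id}: combined SMG mean requested but only "
                    "summary doses without volumes are available; allow the "
                    "equal-volume fallback or choose 'mean'/'sum'"
                )
            smg = float(np.mean(pair))
    return FeatureVector(
        parotid_sum_dose=parotid,
        smg_dose=smg,
        baseline_category=record.baseline_xerostomia,
    )


# ---------------------------------------------------------------------------
# Model updating

def _check_outcome(y: np.ndarray) -> None:
    y = np.asarray(y)
    if y.size == 0 or not set(np.unique(y)) <= {0, 1}:
        raise FittingError("outcome must be non-empty binary 0/1")
    if len(np.unique(y)) < 2:
        raise FittingError("degenerate constant outcome: cannot fit")


def _fit_logit(endog, exog, offset=None):
    """Newton MLE of a logistic model; raises FittingError on separation/non-convergence."""
    try:
        model = sm.GLM(endog, exog, family=sm.families.Binomial(), offset=offset)
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # PerfectSeparation, LinAlgError, ...
        raise FittingError(f"logistic fit failed: {exc}") from exc
    params = np.atleast_1d(res.params)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 50):
        raise FittingError("logistic fit diverged (complete separation suspected)")
    return params, float(res.llf)


def update_model(
    model: NTCPModel,
    lp: np.ndarray,
    y: np.ndarray,
    level: str,
    features: list[FeatureVector] | None = None,
    refit_baseline: bool = False,
) -> NTCPModel:
    """Refit the model at one update level and fold the fit back into coefficients.

    ``lp`` must be the original model's linear predictors on the data.

    * ``intercept``: logit p = a + lp (offset); folded as intercept + a.
    * ``recalibration``: logit p = a + b*lp; folded as intercept a + b*b0,
      dose coefficients b*bi and baseline scores b*score, so evaluating the
      folded model reproduces a + b*lp exactly.
    * ``revision``: full refit of the intercept and both dose coefficients
      on the (transformed) dose features, keeping baseline scores fixed as
      an offset; with ``refit_baseline`` and observed baseline variation the
      category scores are re-estimated as free coefficients.
    """
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_outcome(y)
    if level == "intercept":
        params, _ = _fit_logit(y, np.ones((len(y), 1)), offset=lp)
        return replace(
            model,
            intercept=model.intercept + params[0],
            provenance="intercept-updated",
        )
    if level == "recalibration":
        params, _ = _fit_logit(y, np.column_stack([np.ones(len(y)), lp]))
        a, b = params
        return replace(
            model,
            intercept=a + b * model.intercept,
            coef_parotid=b * model.coef_parotid,
            coef_smg=b * model.coef_smg,
            baseline_scores={k: b * v for k, v in model.baseline_scores.items()},
            provenance="recalibrated",
        )
    if level == "revision":
        if features is None:
            raise ConfigError("revision requires the raw feature vectors")
        t = model.dose_transform
        xp = _transform(np.array([f.parotid_sum_dose for f in features]), t)
        xs = _transform(np.array([f.smg_dose for f in features]), t)
        cats = [
            "none" if f.baseline_category == "missing" else f.baseline_category
            for f in features
        ]
        score_col = np.array([baseline_score(model, c) for c in cats])
        score_varies = len(np.unique(score_col)) > 1
        categorical = refit_baseline and len(set(cats)) > 1
        cols = [np.ones(len(y)), xp, xs]
        levels_present: list[str] = []
        if categorical:
            # free effect per observed baseline category
            levels_present = [c for c in ("mild", "moderate_severe") if c in cats]
            for cat in levels_present:
                cols.append(np.array([1.0 if c == cat else 0.0 for c in cats]))
        elif score_varies:
            # single free coefficient on the original score keeps the
            # recalibrated model nested inside the revision
            cols.append(score_col)
        offset = None if (categorical or score_varies) else score_col
        params, _ = _fit_logit(y, np.column_stack(cols), offset=offset)
        scores = dict(model.baseline_scores)
        if categorical:
            scores = {"none": 0.0, "mild": 0.0, "moderate_severe": 0.0, **{
                cat: float(params[3 + i]) for i, cat in enumerate(levels_present)
            }}
        elif score_varies:
            scores = {k: float(params[3]) * v for k, v in model.baseline_scores.items()}
        return replace(
            model,
            intercept=float(params[0]),
            coef_parotid=float(params[1]),
            coef_smg=float(params[2]),
            baseline_scores=scores,
            provenance="revised",
        )
    raise ConfigError(f"unknown update level {level!r}")
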