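"""Decision-curve analysis: confusion counts and net benefit by threshold.

At a probability threshold t, treating every patient with predicted risk
p >= t yields net benefit NB = TP/n - (FP/n) * t/(1-t): true positives per
patient, with false positives discounted at the odds of the threshold.
Reference policies are treat-all (NB = prevalence - (1-prevalence)*t/(1-t))
and treat-none (NB = 0). The clinically anchored threshold here is 30%,
the risk the model assigns at typical salivary-gland dose constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class ThresholdPerformance:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    net_benefit: float
    net_benefit_treat_all: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _check_threshold(t: float) -> None:
    if not 0 < t < 1:
        raise DataError(f"threshold must be strictly inside (0, 1), got {t}")


def confusion_at_threshold(p, y, t: float) -> ThresholdPerformance:
    """Counts under the rule 'predicted positive iff p >= t', with net benefit."""
    _check_threshold(t)
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = p >= t
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))
    n = len(y)
    prevalence = float(np.mean(y))
    w = t / (1.0 - t)
    return ThresholdPerformance(
        threshold=t,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        net_benefit=tp / n - (fp / n) * w,
        net_benefit_treat_all=prevalence - (1.0 - prevalence) * w,
    )


def net_benefit(p, y, t: float) -> float:
    """NB = TP/n - (FP/n) * t/(1-t) at threshold t."""
    return confusion_at_threshold(p, y, t).net_benefit


def default_threshold_grid() -> np.ndarray:
    """0.05 to 0.60 in steps of 0.05; always contains the 0.30 anchor."""
    return np.round(np.arange(0.05, 0.601, 0.05), 10)


def decision_curve(p, y, thresholds=None) -> pd.DataFrame:
    """One row per threshold: counts, sensitivity/specificity, model NB, treat-all NB."""
    if thresholds is None:
        thresholds = default_threshold_grid()
    rows = [confusion_at_threshold(p, y, float(t)).to_dict() for t in np.sort(np.asarray(thresholds, dtype=float))]
    df = pd.DataFrame(rows)
    df["net_benefit_treat_none"] = 0.0
    return df
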