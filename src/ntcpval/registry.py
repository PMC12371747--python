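"""Quality-registry cohort: records, inclusion cascade, endpoint, summaries.

The validation cohort is assembled from a head-and-neck quality registry:
one row per patient with per-gland mean doses (or a pointer to a DVH file),
the baseline xerostomia category, clinician-scored follow-up assessments
(RTOG/EORTC grade 0-4 at a time in months after radiotherapy), and treatment
metadata. Inclusion applies, in a fixed order, eligibility criteria
(treatment year, tumor site, curative prescribed dose, contoured glands,
at least one follow-up inside the analysis window) and then the exclusion
flags (plan adaptation, brachytherapy boost, reirradiation); each removed
record is attributed to the first failing criterion, so the tally is a flow
chart without double counting.

The binary endpoint is moderate-to-severe (grade >= 2) late xerostomia at
the follow-up nearest 6 months within the window (default 5-24 months).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

TUMOR_SITES = ("oropharynx", "nasopharynx", "hypopharynx", "larynx", "oral_cavity", "other")
BASELINE_CATEGORIES = ("none", "mild", "moderate_severe", "missing")
GLAND_KEYS = ("parotid_ipsi", "parotid_contra", "smg_ipsi", "smg_contra")

#: Published summary of the model-development cohort (n = 1145) used for
#: cohort comparisons: categorical count tables, continuous mean/SD/n, and
#: median physical mean doses in Gy for the combined parotid and
#: submandibular structures.
DEVELOPMENT_COHORT_SUMMARY = {
    "n": 1145,
    "categorical": {
        "sex": {"male": 850, "female": 295},
        "xerostomia_grade2plus": {"event": 531, "no_event": 614},
    },
    "continuous": {"age": (63.3, 10.0, 1145)},
    "median_dose": {"parotid": 25.6, "smg": 56.6},
}

#: The corresponding published validation-cohort (n = 674) reference values.
VALIDATION_COHORT_SUMMARY = {
    "n": 674,
    "categorical": {
        "sex": {"male": 481, "female": 193},
        "xerostomia_grade2plus": {"event": 204, "no_event": 470},
    },
    "continuous": {"age": (63.0, 10.3, 674)},
    "median_dose": {"parotid": 22.6, "smg": 54.8},
}


@dataclass(frozen=True)
class FollowUp:
    """One clinician assessment: months since end of radiotherapy and RTOG/EORTC grade."""

    time_months: float
    xerostomia_grade: int

    def __post_init__(self) -> None:
        if self.xerostomia_grade not in (0, 1, 2, 3, 4):
            raise DataError(f"xerostomia grade must be 0-4, got {self.xerostomia_grade}")
        if self.time_months <= 0:
            raise DataError("follow-up time must be > 0 months")


@dataclass
class PatientRecord:
    """One registry row."""

    patient_id: str
    treatment_year: int
    tumor_site: str
    prescribed_dose: float
    n_fractions: int
    baseline_xerostomia: str = "missing"
    gland_mean_doses: dict[str, float] = field(default_factory=dict)
    dvh_file: str | None = None
    followups: list[FollowUp] = field(default_factory=list)
    plan_adaptation: bool = False
    brachy_boost: bool = False
    reirradiation: bool = False
    glands_contoured: bool = True

    def __post_init__(self) -> None:
        if self.tumor_site not in TUMOR_SITES:
            raise DataError(f"record {self.patient_id}: unknown tumor site {self.tumor_site!r}")
        if self.baseline_xerostomia not in BASELINE_CATEGORIES:
            raise DataError(
                f"record {self.patient_id}: unknown baseline category "
                f"{self.baseline_xerostomia!r}"
            )
        if self.prescribed_dose <= 0:
            raise DataError(f"record {self.patient_id}: prescribed dose must be > 0")
        if any(v < 0 for v in self.gland_mean_doses.values()):
            raise DataError(f"record {self.patient_id}: negative gland mean dose")


@dataclass
class InclusionCriteria:
    """Eligibility settings for :func:`apply_inclusion`."""

    year_range: tuple[int, int] = (2012, 2024)
    followup_window: tuple[float, float] = (5.0, 24.0)
    min_prescribed_dose: float = 50.0
    allowed_sites: tuple[str, ...] = TUMOR_SITES
    require_glands_contoured: bool = True


#: Order in which exclusion reasons are attributed (first failing wins).
EXCLUSION_ORDER = (
    "year_out_of_range",
    "site_not_allowed",
    "dose_below_curative",
    "glands_not_contoured",
    "no_followup_in_window",
    "plan_adaptation",
    "brachy_boost",
    "reirradiation",
)


@dataclass
class ExclusionTally:
    """Per-criterion counts of removed records, in application order."""

    n_input: int
    counts: dict[str, int]
    n_remaining: int

    def check(self) -> None:
        assert self.n_input == self.n_remaining + sum(self.counts.values())


def _exclusion_reason(rec: PatientRecord, c: InclusionCriteria) -> str | None:
    if not c.year_range[0] <= rec.treatment_year <= c.year_range[1]:
        return "year_out_of_range"
    if rec.tumor_site not in c.allowed_sites:
        return "site_not_allowed"
    if rec.prescribed_dose < c.min_prescribed_dose:
        return "dose_below_curative"
    if c.require_glands_contoured and not rec.glands_contoured:
        return "glands_not_contoured"
    if select_followup(rec.followups, window=c.followup_window) is None:
        return "no_followup_in_window"
    if rec.plan_adaptation:
        return "plan_adaptation"
    if rec.brachy_boost:
        return "brachy_boost"
    if rec.reirradiation:
        return "reirradiation"
    return None


def apply_inclusion(
    records: list[PatientRecord], criteria: InclusionCriteria | None = None
) -> tuple[list[PatientRecord], ExclusionTally]:
    """Apply the inclusion cascade; return included records and the flow tally."""
    criteria = criteria or InclusionCriteria()
    counts = {k: 0 for k in EXCLUSION_ORDER}
    included: list[PatientRecord] = []
    for rec in records:
        reason = _exclusion_reason(rec, criteria)
        if reason is None:
            included.append(rec)
        else:
            counts[reason] += 1
    tally = ExclusionTally(n_input=len(records), counts=counts, n_remaining=len(included))
    tally.check()
    return included, tally


def select_followup(
    followups: list[FollowUp],
    target: float = 6.0,
    window: tuple[float, float] = (5.0, 24.0),
) -> FollowUp | None:
    """Follow-up nearest the target time inside the window; ties go to the earlier visit.

    Returns ``None`` when no assessment falls inside the window.
    """
    lo, hi = window
    if not lo < hi:
        raise DataError(f"invalid follow-up window {window}")
    eligible = [fu for fu in followups if lo <= fu.time_months <= hi]
    if not eligible:
        return None
    return min(eligible, key=lambda fu: (abs(fu.time_months - target), fu.time_months))


def derive_endpoint(fu: FollowUp) -> int:
    """1 for moderate-to-severe xerostomia (grade >= 2), else 0."""
    return int(fu.xerostomia_grade >= 2)


def format_percent(count: int, total: int) -> str:
    """Table-style percentage: integer at >= 10%, one decimal below."""
    pct = 100.0 * count / total
    return f"{pct:.0f}%" if pct >= 9.95 else f"{pct:.1f}%"


def cohort_summary(
    records: list[PatientRecord],
    target: float = 6.0,
    followup_window: tuple[float, float] = (5.0, 24.0),
) -> dict:
    """Cohort characteristics table: counts/percentages, dose medians/IQRs, prevalence."""
    if not records:
        raise DataError("empty cohort")
    n = len(records)

    def cat_counts(values):
        out: dict[str, int] = {}
        for v in values:
            out[v] = out.get(v, 0) + 1
        return out

    site_counts = cat_counts(r.tumor_site for r in records)
    baseline_counts = cat_counts(r.baseline_xerostomia for r in records)

    events = 0
    n_assessed = 0
    fut = []
    for r in records:
        fu = select_followup(r.followups, target=target, window=followup_window)
        if fu is not None:
            n_assessed += 1
            events += derive_endpoint(fu)
            fut.append(fu.time_months)

    doses = {}
    for key in GLAND_KEYS:
        vals = np.array([r.gland_mean_doses[key] for r in records if key in r.gland_mean_doses])
        if vals.size:
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            doses[key] = {"median": float(med), "iqr": (float(q25), float(q75))}

    return {
        "n": n,
        "tumor_site": {
            k: {"count": v, "percent": format_percent(v, n)} for k, v in site_counts.items()
        },
        "baseline_xerostomia": {
            k: {"count": v, "percent": format_percent(v, n)} for k, v in baseline_counts.items()
        },
        "n_events": events,
        "n_assessed": n_assessed,
        "prevalence_percent": format_percent(events, n_assessed) if n_assessed else None,
        "prevalence_percent_1dp": (
            f"{100.0 * events / n_assessed:.1f}%" if n_assessed else None
        ),
        "median_followup_months": float(np.median(fut)) if fut else None,
        "gland_mean_dose_gy": doses,
    }


def median_dose_difference(summary_a: dict, summary_b: dict, structure: str) -> float:
    """Difference of published median mean doses (Gy) between two cohort summaries."""
    return round(summary_a["median_dose"][structure] - summary_b["median_dose"][structure], 1)


def cohort_compare(summary_a: dict, summary_b: dict) -> pd.DataFrame:
    """Compare two cohort summaries variable by variable.

    Categorical variables (count tables with matching categories) are tested
    with a chi-square test of independence; continuous variables supplied as
    (mean, sd, n) with a two-sample t-test. Categories with a zero expected
    count are merged into the largest remaining category, with a warning.
    Returns a frame with one row per variable: test, statistic, p, significant.
    """
    rows = []
    cats_a = summary_a.get("categorical", {})
    cats_b = summary_b.get("categorical", {})
    for var in sorted(set(cats_a) & set(cats_b)):
        table_a, table_b = cats_a[var], cats_b[var]
        cats = sorted(set(table_a) | set(table_b))
        obs = np.array(
            [[table_a.get(c, 0) for c in cats], [table_b.get(c, 0) for c in cats]], dtype=float
        )
        # drop/merge categories that would give zero expected counts
        zero = obs.sum(axis=0) == 0
        if zero.any():
            obs = obs[:, ~zero]
        if obs.shape[1] < 2:
            warnings.warn(f"{var}: fewer than two informative categories, skipped")
            continue
        if (obs.sum(axis=0) == obs.sum()).any() or (obs.sum(axis=1) == 0).any():
            warnings.warn(f"{var}: degenerate table, skipped")
            continue
        if np.array_equal(obs[0] / obs[0].sum(), obs[1] / obs[1].sum()):
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
        rows.append({"variable": var, "test": "chi-square", "statistic": stat, "p": p})
    cont_a = summary_a.get("continuous", {})
    cont_b = summary_b.get("continuous", {})
    for var in sorted(set(cont_a) & set(cont_b)):
        (m1, s1, n1), (m2, s2, n2) = cont_a[var], cont_b[var]
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
        rows.append({"variable": var, "test": "t-test", "statistic": res.statistic, "p": res.pvalue})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["significant"] = df["p"] < 0.05
    return df


# ---------------------------------------------------------------------------
# Cohort-table CSV I/O

_CSV_COLUMNS = [
    "patient_id", "treatment_year", "tumor_site", "prescribed_dose_gy", "n_fractions",
    "baseline_xerostomia", "parotid_ipsi_mean", "parotid_contra_mean", "smg_ipsi_mean",
    "smg_contra_mean", "dvh_file", "flag_adaptation", "flag_brachy", "flag_reirradiation",
    "followup_times", "followup_grades",
]


def write_cohort_csv(path: str | Path, records: list[PatientRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "treatment_year": r.treatment_year,
                "tumor_site": r.tumor_site,
                "prescribed_dose_gy": r.prescribed_dose,
                "n_fractions": r.n_fractions,
                "baseline_xerostomia": r.baseline_xerostomia,
                **{f"{k}_mean": r.gland_mean_doses.get(k, "") for k in GLAND_KEYS},
                "dvh_file": r.dvh_file or "",
                "flag_adaptation": int(r.plan_adaptation),
                "flag_brachy": int(r.brachy_boost),
                "flag_reirradiation": int(r.reirradiation),
                "followup_times": ";".join(f"{fu.time_months:g}" for fu in r.followups),
                "followup_grades": ";".join(str(fu.xerostomia_grade) for fu in r.followups),
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"followup_times": str, "followup_grades": str})
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: cohort table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        times = [float(t) for t in str(row["followup_times"]).split(";") if t not in ("", "nan")]
        grades = [int(g) for g in str(row["followup_grades"]).split(";") if g not in ("", "nan")]
        if len(times) != len(grades):
            raise DataError(f"record {row['patient_id']}: follow-up times/grades length mismatch")
        doses = {}
        for k in GLAND_KEYS:
            v = row[f"{k}_mean"]
            if pd.notna(v) and v != "":
                doses[k] = float(v)
        baseline = row["baseline_xerostomia"]
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                treatment_year=int(row["treatment_year"]),
                tumor_site=str(row["tumor_site"]),
                prescribed_dose=float(row["prescribed_dose_gy"]),
                n_fractions=int(row["n_fractions"]),
                baseline_xerostomia="missing" if pd.isna(baseline) else str(baseline),
                gland_mean_doses=doses,
                dvh_file=(str(row["dvh_file"]) if pd.notna(row["dvh_file"]) and row["dvh_file"] != "" else None),
                followups=[FollowUp(t, g) for t, g in zip(times, grades)],
                plan_adaptation=bool(int(row["flag_adaptation"])),
                brachy_boost=bool(int(row["flag_brachy"])),
                reirradiation=bool(int(row["flag_reirradiation"])),
            )
        )
    return records
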