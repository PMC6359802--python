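"""Clinical data model, response classification and cohort splitting.

The cohort is an ICI-treated stage-IV NSCLC population. Each patient
carries RECIST best response, survival from first ICI dose, vital status
and follow-up. Patients are classified into disease control (DC: CR/PR at
any survival, or SD with >= 12 months survival) versus no disease control
(NDC: PD, or SD with < 12 months survival); patients who die within 90
days of first dose are excluded (rapid progressors cannot be separated
from poor performance status), as are patients alive with < 90 days of
follow-up and no evaluable response.

The bulk container is a pandas DataFrame with the columns of
:data:`CLINICAL_COLUMNS`; :class:`PatientRecord` is the single-row view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds

# response labels
DC = "DC"
NDC = "NDC"
EXCLUDED_EARLY_DEATH = "excluded_early_death"
EXCLUDED_INSUFFICIENT_FOLLOWUP = "excluded_insufficient_followup"
NOT_EVALUABLE = "not_evaluable"

RESPONSE_LABELS = (DC, NDC, EXCLUDED_EARLY_DEATH,
                   EXCLUDED_INSUFFICIENT_FOLLOWUP, NOT_EVALUABLE)

BEST_RESPONSES = ("CR", "PR", "SD", "PD", "not_evaluable")
VITAL_STATUSES = ("alive", "dead")

CLINICAL_COLUMNS = [
    "patient_id", "institution", "age_years", "age_category", "sex", "race",
    "histology", "ici_agent", "pd_l1_tps", "best_response",
    "survival_months", "vital_status", "followup_months",
]


@dataclass
class PatientRecord:
    """One patient's clinical covariates and outcome data."""

    patient_id: str
    institution: str
    age_years: float
    age_category: str
    sex: str
    race: str
    histology: str
    ici_agent: str
    pd_l1_tps: Optional[float]
    best_response: str
    survival_months: float
    vital_status: str
    followup_months: float
    not_evaluable_reason: str = ""

    def __post_init__(self) -> None:
        if self.survival_months < 0 or self.followup_months < 0:
            raise ValueError(f"{self.patient_id}: negative time")
        if self.pd_l1_tps is not None and not np.isnan(self.pd_l1_tps):
            if not (0.0 <= self.pd_l1_tps <= 100.0):
                raise ValueError(f"{self.patient_id}: TPS outside [0, 100]")
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"{self.patient_id}: bad vital_status {self.vital_status!r}")


@dataclass(frozen=True)
class CohortSplit:
    """Institution-based train/test partition of the evaluable cohort."""

    training_ids: frozenset
    test_ids: frozenset
    test_institution: str

    @property
    def n_training(self) -> int:
        return len(self.training_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)


def classify_response(best_response: str,
                      survival_months: float,
                      followup_months: float,
                      vital_status: str,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Assign one of the five response labels to a patient.

    Order of the rules matters: the 90-day early-death exclusion applies
    regardless of the recorded best response.
    """
    if best_response not in BEST_RESPONSES:
        raise ValueError(
            f"unknown best_response {best_response!r}; expected one of {BEST_RESPONSES}"
        )
    if vital_status not in VITAL_STATUSES:
        raise ValueError(f"unknown vital_status {vital_status!r}")
    if survival_months < 0 or followup_months < 0:
        raise ValueError("survival_months and followup_months must be >= 0")

    cut = thresholds.early_exclusion_months
    if vital_status == "dead" and survival_months < cut:
        return EXCLUDED_EARLY_DEATH
    if best_response == "not_evaluable":
        if vital_status == "alive" and followup_months < cut:
            return EXCLUDED_INSUFFICIENT_FOLLOWUP
        return NOT_EVALUABLE
    if best_response in ("CR", "PR"):
        if thresholds.dc_requires_12mo_for_cr_pr:
            return DC if survival_months >= thresholds.sd_dc_min_months else NDC
        return DC
    if best_response == "SD":
        return DC if survival_months >= thresholds.sd_dc_min_months else NDC
    return NDC  # PD


def classify_cohort(clinical: pd.DataFrame,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.Series:
    """Vector of response labels indexed by patient_id."""
    labels = [
        classify_response(row.best_response, row.survival_months,
                          row.followup_months, row.vital_status, thresholds)
        for row in clinical.itertuples()
    ]
    return pd.Series(labels, index=pd.Index(clinical["patient_id"], name="patient_id"),
                     name="response_label")


def eligible_for_survival(clinical: pd.DataFrame,
                          thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Patients passing the 90-day exclusions (the survival-analysis set).

    A superset of the response-evaluable set: it keeps patients whose
    response was not evaluable but who have adequate survival follow-up.
    """
    if clinical.empty:
        return clinical.copy()
    labels = classify_cohort(clinical, thresholds)
    keep = ~labels.isin([EXCLUDED_EARLY_DEATH, EXCLUDED_INSUFFICIENT_FOLLOWUP])
    return clinical.loc[keep.to_numpy()].copy()


def evaluable_for_response(clinical: pd.DataFrame,
                           thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Patients entering outcome statistics: label in {DC, NDC}."""
    if clinical.empty:
        return clinical.copy()
    labels = classify_cohort(clinical, thresholds)
    keep = labels.isin([DC, NDC])
    return clinical.loc[keep.to_numpy()].copy()


def split_by_institution(evaluable: pd.DataFrame) -> CohortSplit:
    """Hold out the single largest contributing institution as the test set.

    Ties on the largest count are broken lexicographically (earliest
    institution name wins) with a warning.
    """
    if evaluable.empty:
        raise ValueError("cannot split an empty cohort")
    counts = evaluable.groupby("institution")["patient_id"].count()
    if len(counts) < 2:
        raise ValueError("cohort has a single institution; no train/test split possible")
    top = counts.max()
    winners = sorted(counts.index[counts == top])
    if len(winners) > 1:
        warnings.warn(
            f"institutions {winners} tie for largest ({top} patients); "
            f"choosing {winners[0]!r} lexicographically",
            stacklevel=2,
        )
    test_inst = winners[0]
    mask = evaluable["institution"] == test_inst
    return CohortSplit(
        training_ids=frozenset(evaluable.loc[~mask, "patient_id"]),
        test_ids=frozenset(evaluable.loc[mask, "patient_id"]),
        test_institution=test_inst,
    )


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table (CSV, header per CLINICAL_COLUMNS).

    Missing TPS is an empty field and becomes NaN.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "institution": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df["pd_l1_tps"] = pd.to_numeric(df["pd_l1_tps"], errors="coerce")
    validate_clinical(df)
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def validate_clinical(df: pd.DataFrame) -> None:
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicated patient_id values: {dupes}")
    if (df["survival_months"] < 0).any() or (df["followup_months"] < 0).any():
        raise ValueError("negative survival or follow-up times")
    tps = df["pd_l1_tps"].dropna()
    if ((tps < 0) | (tps > 100)).any():
        raise ValueError("TPS values outside [0, 100]")
    bad = set(df["best_response"]) - set(BEST_RESPONSES)
    if bad:
        raise ValueError(f"unknown best_response values: {sorted(bad)}")
    bad = set(df["vital_status"]) - set(VITAL_STATUSES)
    if bad:
        raise ValueError(f"unknown vital_status values: {sorted(bad)}")


def disposition_counts(clinical: pd.DataFrame,
                       thresholds: Thresholds = DEFAULT_THRESHOLDS) -> dict:
    """Patient counts at every filter step (a disposition-diagram summary)."""
    labels = classify_cohort(clinical, thresholds)
    vc = labels.value_counts()
    n_eligible = int(len(clinical) - vc.get(EXCLUDED_EARLY_DEATH, 0)
                     - vc.get(EXCLUDED_INSUFFICIENT_FOLLOWUP, 0))
    return {
        "n_total": int(len(clinical)),
        "n_excluded_early_death": int(vc.get(EXCLUDED_EARLY_DEATH, 0)),
        "n_excluded_insufficient_followup": int(vc.get(EXCLUDED_INSUFFICIENT_FOLLOWUP, 0)),
        "n_survival_eligible": n_eligible,
        "n_not_evaluable": int(vc.get(NOT_EVALUABLE, 0)),
        "n_response_evaluable": int(vc.get(DC, 0) + vc.get(NDC, 0)),
        "n_dc": int(vc.get(DC, 0)),
        "n_ndc": int(vc.get(NDC, 0)),
    }
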