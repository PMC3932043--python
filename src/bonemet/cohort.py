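"""Inclusion/exclusion cascade and follow-up censoring.

A patient enters the analysis cohort iff, in this order:

1. age at diagnosis >= 66 years;
2. diagnosis year within the study accrual years (2005-2007);
3. AJCC stage M1 (M1a/M1b/M1c) — metastatic at diagnosis;
4. Medicare Parts A and B both active for every one of the 13 calendar
   months from 12 months before diagnosis through the diagnosis month;
5. no HMO enrollment in any of those 13 months (HMO claims are unreliable);
6. no other cancer within 5 years before the prostate-cancer diagnosis.

Each excluded patient is attributed the first failing rule, so the
exclusion log partitions the excluded set and the cascade is auditable.
Retained patients are censored at the earliest of: first post-diagnosis
HMO month, first post-diagnosis month without both Parts A and B, or the
study end (December 2009).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import EnrollmentSpan, RegistryRecord
from .timeutil import parse_month

logger = logging.getLogger(__name__)

#: Fixed attribution order: first failing rule wins.
EXCLUSION_REASONS = (
    "age_under_66",
    "dx_year_out_of_range",
    "not_M1",
    "no_continuous_AB",
    "hmo_baseline",
    "prior_cancer",
)

STUDY_END = pd.Period("2009-12", freq="M")
BASELINE_MONTHS = 12  # months of required enrollment before the dx month
MIN_AGE = 66
DX_YEARS = (2005, 2007)


@dataclass(frozen=True)
class CohortMember:
    """A retained patient with their follow-up bounds."""

    patient_id: str
    dx_month: pd.Period
    censor_month: pd.Period
    registry_bm: bool

    def __post_init__(self):
        if self.censor_month < self.dx_month:
            raise ValueError("censor month precedes diagnosis month")


EnrollmentIndex = dict[tuple[str, int], tuple[bool, bool, bool]]


def index_enrollment(spans: Iterable[EnrollmentSpan]) -> EnrollmentIndex:
    """(patient_id, month ordinal) -> (part_a, part_b, hmo) lookup."""
    return {
        (s.patient_id, s.month.ordinal): (s.part_a, s.part_b, s.hmo) for s in spans
    }


def _exclusion_reason(
    record: RegistryRecord,
    enrollment: EnrollmentIndex,
    dx_years: tuple[int, int],
    min_age: int,
) -> str | None:
    if record.age_at_dx < min_age:
        return "age_under_66"
    if not (dx_years[0] <= record.dx_month.year <= dx_years[1]):
        return "dx_year_out_of_range"
    if record.ajcc_m not in ("M1a", "M1b", "M1c"):
        return "not_M1"
    baseline = [
        enrollment.get((record.patient_id, record.dx_month.ordinal - k))
        for k in range(BASELINE_MONTHS, -1, -1)
    ]
    if any(row is None or not (row[0] and row[1]) for row in baseline):
        if all(row is None for row in baseline):
            logger.warning("patient %s has no enrollment rows", record.patient_id)
        return "no_continuous_AB"
    if any(row[2] for row in baseline):
        return "hmo_baseline"
    if record.prior_cancer_within_5y:
        return "prior_cancer"
    return None


def censor_month(
    record: RegistryRecord,
    enrollment: EnrollmentIndex,
    study_end: pd.Period = STUDY_END,
) -> pd.Period:
    """Earliest of post-diagnosis HMO entry, A/B loss, or study end.

    A missing enrollment row after diagnosis counts as loss of coverage.
    """
    study_end = parse_month(study_end)
    month = record.dx_month + 1
    while month <= study_end:
        row = enrollment.get((record.patient_id, month.ordinal))
        if row is None or not (row[0] and row[1]) or row[2]:
            return month
        month += 1
    return study_end


def apply_inclusion_exclusion(
    registry: Sequence[RegistryRecord],
    enrollment_spans: Iterable[EnrollmentSpan],
    study_end: pd.Period = STUDY_END,
    dx_years: tuple[int, int] = DX_YEARS,
    min_age: int = MIN_AGE,
) -> tuple[list[CohortMember], pd.DataFrame]:
    """Apply the cascade; returns (retained cohort, per-patient exclusion log).

    The log has one row per input patient with an ``exclusion_reason``
    column that is empty for retained patients, so retained + excluded
    always equals the input count and reasons partition the excluded set.
    """
    enrollment = index_enrollment(enrollment_spans)
    study_end = parse_month(study_end)
    cohort: list[CohortMember] = []
    log_rows = []
    for record in registry:
        reason = _exclusion_reason(record, enrollment, dx_years, min_age)
        log_rows.append(
            {"patient_id": record.patient_id, "exclusion_reason": reason or ""}
        )
        if reason is None:
            cohort.append(
                CohortMember(
                    patient_id=record.patient_id,
                    dx_month=record.dx_month,
                    censor_month=censor_month(record, enrollment, study_end),
                    registry_bm=record.registry_bm,
                )
            )
    log = pd.DataFrame(log_rows, columns=["patient_id", "exclusion_reason"])
    logger.info(
        "cohort selection: %d in, %d retained, %d excluded",
        len(registry),
        len(cohort),
        len(registry) - len(cohort),
    )
    return cohort, log


def exclusion_counts(log: pd.DataFrame) -> pd.Series:
    """Excluded-patient counts by reason, in cascade order."""
    excluded = log[log["exclusion_reason"] != ""]
    return (
        excluded["exclusion_reason"]
        .value_counts()
        .reindex(EXCLUSION_REASONS, fill_value=0)
    )
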