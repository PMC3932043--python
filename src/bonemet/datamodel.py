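"""Domain records shared by all pipeline stages.

Three record types mirror the three linked data sources: the cancer-registry
row (one per patient, month-precision diagnosis), billed claims (one per
service line, day-precision), and Medicare enrollment status by calendar
month.  Records are plain frozen dataclasses; the I/O layer converts them to
and from the delimited-file schemas.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from .codes import CLAIM_SETTINGS, COMORBIDITY_CLASSES, M_STAGES, SERVICE_CATEGORIES
from .timeutil import parse_date, parse_month


@dataclass(frozen=True)
class RegistryRecord:
    """One patient's registry-side facts at diagnosis.

    ``dx_month`` has month precision only — the registry does not release an
    exact diagnosis date.  ``ajcc_m == "M1b"`` is the registry-based
    bone-metastasis measure; M1a is non-regional nodal and M1c other-site
    distant disease.  ``comorbidity_class`` is a pre-computed categorical
    (Charlson class), carried through but never recomputed here.
    """

    patient_id: str
    dx_month: pd.Period
    ajcc_m: str
    age_at_dx: int
    sex: str = "male"
    race: str = "white_nh"
    prior_cancer_within_5y: bool = False
    comorbidity_class: str = "0"
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "dx_month", parse_month(self.dx_month))
        if self.ajcc_m not in M_STAGES:
            raise ValueError(f"unknown AJCC M stage {self.ajcc_m!r}")
        if self.comorbidity_class not in COMORBIDITY_CLASSES:
            raise ValueError(f"unknown comorbidity class {self.comorbidity_class!r}")

    @property
    def registry_bm(self) -> bool:
        """Registry-based bone-metastasis flag (M1b sub-stage)."""
        return self.ajcc_m == "M1b"


@dataclass(frozen=True)
class Claim:
    """One billed service line.

    ``dx_codes`` is the ordered tuple of ICD-9-CM diagnosis codes on the
    claim; position 1 is the primary (discharge) diagnosis.  ``setting``
    distinguishes the three Medicare claim files: inpatient stays,
    facility outpatient services, and physician/supplier (carrier) lines.
    ``is_physician_em`` marks carrier evaluation-and-management visits.
    """

    patient_id: str
    setting: str
    service_date: dt.date
    dx_codes: tuple[str, ...]
    service_category: str = "other"
    is_physician_em: bool = False
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "service_date", parse_date(self.service_date))
        object.__setattr__(self, "dx_codes", tuple(str(c) for c in self.dx_codes))
        if self.setting not in CLAIM_SETTINGS:
            raise ValueError(f"unknown claim setting {self.setting!r}")
        if not self.dx_codes:
            raise ValueError("claim must carry at least one diagnosis code")
        if self.service_category not in SERVICE_CATEGORIES:
            raise ValueError(f"unknown service category {self.service_category!r}")

    def dx_position(self, code: str) -> int | None:
        """1-based position of a diagnosis code on the claim, or None."""
        try:
            return self.dx_codes.index(code) + 1
        except ValueError:
            return None


@dataclass(frozen=True)
class EnrollmentSpan:
    """Part A / Part B / HMO enrollment status for one patient-month."""

    patient_id: str
    month: pd.Period
    part_a: bool
    part_b: bool
    hmo: bool = False
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "month", parse_month(self.month))
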