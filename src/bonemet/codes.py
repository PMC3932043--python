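"""Configurable diagnosis-code and service-category sets.

The bone-metastasis marker in claims is the ICD-9-CM diagnosis code 198.5
("secondary malignant neoplasm of bone and bone marrow").  The procedure side
of the rules is keyed on a ``service_category`` tag rather than raw CPT/HCPCS
codes: the mapping from real procedure codes to categories is left to whoever
prepares the claim extract, and the category sets below are configurable via
a YAML file so code-list variants can be swapped without touching the rules.

ICD-9 codes are stored as strings with an explicit decimal point ("198.5")
and matched exactly, avoiding the 1985 / 198.50 ambiguity of undotted codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Known service-category tags for a claim line.
SERVICE_CATEGORIES: tuple[str, ...] = (
    "psa_test",
    "bone_joint_imaging",
    "bone_biopsy",
    "bone_scan",
    "iv_bisphosphonate",
    "em_visit",
    "radiation",
    "radiopharmaceutical",
    "bmd_test",
    "oncologist_visit",
    "other",
)

CLAIM_SETTINGS: tuple[str, ...] = ("inpatient", "outpatient", "carrier")

M_STAGES: tuple[str, ...] = ("M0", "M1a", "M1b", "M1c")

COMORBIDITY_CLASSES: tuple[str, ...] = ("0", "1", "2+", "missing")


@dataclass(frozen=True)
class CodeSet:
    """Diagnosis codes and service-category sets driving the claim rules.

    Parameters
    ----------
    bm_dx_codes
        ICD-9 diagnosis codes counted as bone-metastasis evidence.
    pairing_categories
        Service categories that count as "procedures used to diagnose or
        treat bone metastasis" for the Approach-2 outpatient pairing arm.
    expanded_categories
        Outpatient test categories usable by the expanded Approach-3 rule.
    diagnostic_categories
        Categories subject to the two-step diagnostic-claim filter.
    """

    bm_dx_codes: frozenset[str] = frozenset({"198.5"})
    pairing_categories: frozenset[str] = frozenset(
        {"bone_scan", "bone_biopsy", "iv_bisphosphonate"}
    )
    expanded_categories: frozenset[str] = frozenset({"psa_test", "bone_joint_imaging"})
    diagnostic_categories: frozenset[str] = frozenset(
        {"bone_scan", "bone_joint_imaging", "bone_biopsy"}
    )

    def __post_init__(self):
        for name in (
            "bm_dx_codes",
            "pairing_categories",
            "expanded_categories",
            "diagnostic_categories",
        ):
            value = getattr(self, name)
            if not value:
                raise ValueError(f"CodeSet.{name} must be non-empty")
            object.__setattr__(self, name, frozenset(value))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {
            key: frozenset(raw[key])
            for key in (
                "bm_dx_codes",
                "pairing_categories",
                "expanded_categories",
                "diagnostic_categories",
            )
            if key in raw
        }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "bm_dx_codes": sorted(self.bm_dx_codes),
            "pairing_categories": sorted(self.pairing_categories),
            "expanded_categories": sorted(self.expanded_categories),
            "diagnostic_categories": sorted(self.diagnostic_categories),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


DEFAULT_CODESET = CodeSet()
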