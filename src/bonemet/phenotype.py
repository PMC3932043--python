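"""Claims-based bone-metastasis classification rules.

Three rules of increasing restrictiveness flag bone metastasis (BM) from a
patient's claim history, each evaluated inside a concurrency window around
the prostate-cancer diagnosis month:

* **Approach 1** (generous): any inpatient, outpatient or carrier claim
  carrying a BM diagnosis code (ICD-9 198.5) in any diagnosis position.
* **Approach 2** (literature-style): an inpatient claim with the BM code as
  primary or secondary discharge diagnosis; OR an outpatient BM-coded claim
  paired with a procedure used to diagnose or treat BM (bone scan, bone
  biopsy, IV bisphosphonate); OR a carrier physician evaluation-and-
  management claim with the BM code.
* **Approach 3** (restrictive): an inpatient BM-coded claim in any position;
  OR at least two outpatient BM-coded claims on distinct dates within 90
  days of each other.

The **expanded Approach 3** additionally accepts two outpatient claims for a
PSA test or bone/joint imaging on distinct dates within 90 days, inside the
window — a sensitivity-improvement variant.

Because the registry's diagnosis anchor has month precision only, the
concurrency window is the set of three calendar months {anchor-1, anchor,
anchor+1}; a claim is in the window iff its service date falls in one of
those months.  "BM ever" re-evaluates the same rule with no upper month
bound (any claim from the month before diagnosis onward).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .codes import DEFAULT_CODESET, CodeSet
from .datamodel import Claim
from .timeutil import month_of, parse_month

#: gap (days) treated as inside a "90-day window"; the boundary is inclusive
DEFAULT_GAP_DAYS = 90


@dataclass(frozen=True)
class Window:
    """Month-level claim window anchored at the diagnosis month.

    mode="concurrent": the three months {anchor-1, anchor, anchor+1}.
    mode="ever": every month from anchor-1 onward (no upper bound).
    """

    anchor: pd.Period
    mode: str = "concurrent"

    def __post_init__(self):
        object.__setattr__(self, "anchor", parse_month(self.anchor))
        if self.mode not in ("concurrent", "ever"):
            raise ValueError(f"unknown window mode {self.mode!r}")

    @property
    def months(self) -> tuple[pd.Period, ...]:
        if self.mode != "concurrent":
            raise ValueError("unbounded window has no finite month set")
        return (self.anchor - 1, self.anchor, self.anchor + 1)

    def contains(self, date: dt.date) -> bool:
        ordinal = month_of(date).ordinal
        if self.mode == "ever":
            return ordinal >= self.anchor.ordinal - 1
        return abs(ordinal - self.anchor.ordinal) <= 1


@dataclass(frozen=True)
class BmStatus:
    """Per-patient flags for every classification rule.

    Invariants (hold for any claim history): a2 ⇒ a1, a3 ⇒ a1,
    a3 ⇒ a3_expanded, and every concurrent flag ⇒ bm_ever of the same rule.
    """

    patient_id: str
    a1: bool
    a2: bool
    a3: bool
    a3_expanded: bool
    bm_ever: bool


def _has_bm_code(claim: Claim, codeset: CodeSet) -> bool:
    return any(code in codeset.bm_dx_codes for code in claim.dx_codes)


def _in_window(claims: Iterable[Claim], window: Window) -> list[Claim]:
    return [c for c in claims if window.contains(c.service_date)]


def _dates_within_gap(dates: set[dt.date], gap_days: int) -> bool:
    """True iff some pair of distinct dates is at most gap_days apart."""
    if len(dates) < 2:
        return False
    ordered = sorted(dates)
    return any(
        (later - earlier).days <= gap_days
        for earlier, later in zip(ordered, ordered[1:])
    )


def classify_a1(
    claims: Sequence[Claim], window: Window, codeset: CodeSet = DEFAULT_CODESET
) -> bool:
    """Any in-window claim, any setting, BM code in any diagnosis position."""
    return any(_has_bm_code(c, codeset) for c in _in_window(claims, window))


def classify_a2(
    claims: Sequence[Claim], window: Window, codeset: CodeSet = DEFAULT_CODESET
) -> bool:
    """Inpatient primary/secondary BM code, OR paired outpatient BM claim,
    OR carrier physician E&M claim with the BM code.

    "Paired" is satisfied either by one outpatient claim carrying both the
    BM code and a pairing-category service, or by a same-date outpatient
    procedure claim of a pairing category.
    """
    in_window = _in_window(claims, window)
    pairing_dates = {
        c.service_date
        for c in in_window
        if c.setting == "outpatient" and c.service_category in codeset.pairing_categories
    }
    for claim in in_window:
        if not _has_bm_code(claim, codeset):
            continue
        if claim.setting == "inpatient":
            if any(code in codeset.bm_dx_codes for code in claim.dx_codes[:2]):
                return True
        elif claim.setting == "outpatient":
            if (
                claim.service_category in codeset.pairing_categories
                or claim.service_date in pairing_dates
            ):
                return True
        elif claim.setting == "carrier" and claim.is_physician_em:
            return True
    return False


def classify_a3(
    claims: Sequence[Claim],
    window: Window,
    codeset: CodeSet = DEFAULT_CODESET,
    gap_days: int = DEFAULT_GAP_DAYS,
) -> bool:
    """Inpatient BM code any position, OR two outpatient BM claims on
    distinct dates at most ``gap_days`` apart, all inside the window.

    Multiple claims on the same service date count once (duplicate billing
    lines must not satisfy the two-claim requirement).
    """
    in_window = _in_window(claims, window)
    if any(c.setting == "inpatient" and _has_bm_code(c, codeset) for c in in_window):
        return True
    outpatient_dates = {
        c.service_date
        for c in in_window
        if c.setting == "outpatient" and _has_bm_code(c, codeset)
    }
    return _dates_within_gap(outpatient_dates, gap_days)


def classify_a3_expanded(
    claims: Sequence[Claim],
    window: Window,
    codeset: CodeSet = DEFAULT_CODESET,
    gap_days: int = DEFAULT_GAP_DAYS,
) -> bool:
    """Approach 3, OR two in-window outpatient PSA / bone-joint-imaging
    claims on distinct dates at most ``gap_days`` apart.

    The two qualifying test claims may be of either expanded category in any
    combination (mixed pairs count).
    """
    if classify_a3(claims, window, codeset, gap_days):
        return True
    test_dates = {
        c.service_date
        for c in _in_window(claims, window)
        if c.setting == "outpatient"
        and c.service_category in codeset.expanded_categories
    }
    return _dates_within_gap(test_dates, gap_days)


_APPROACHES: dict[str, Callable] = {
    "a1": classify_a1,
    "a2": classify_a2,
    "a3": classify_a3,
    "a3_expanded": classify_a3_expanded,
}


def bm_ever(
    claims: Sequence[Claim],
    dx_month: str | pd.Period,
    codeset: CodeSet = DEFAULT_CODESET,
    approach: str = "a3",
) -> bool:
    """Rule evaluated over all claims from the month before diagnosis onward."""
    window = Window(anchor=parse_month(dx_month), mode="ever")
    return _APPROACHES[approach](claims, window, codeset)


def classify_patient(
    patient_id: str,
    claims: Sequence[Claim],
    dx_month: str | pd.Period,
    codeset: CodeSet = DEFAULT_CODESET,
    ever_approach: str = "a3",
) -> BmStatus:
    """All concurrent flags plus the "ever" flag for one patient."""
    window = Window(anchor=parse_month(dx_month))
    return BmStatus(
        patient_id=patient_id,
        a1=classify_a1(claims, window, codeset),
        a2=classify_a2(claims, window, codeset),
        a3=classify_a3(claims, window, codeset),
        a3_expanded=classify_a3_expanded(claims, window, codeset),
        bm_ever=bm_ever(claims, dx_month, codeset, approach=ever_approach),
    )


def classify_cohort(
    dx_months: dict[str, pd.Period],
    claims_by_patient: dict[str, list[Claim]],
    codeset: CodeSet = DEFAULT_CODESET,
) -> pd.DataFrame:
    """Classify every patient; returns one row per patient id.

    ``dx_months`` maps retained patient ids to their diagnosis month; ids
    absent from ``claims_by_patient`` are classified from an empty history
    (all flags false).
    """
    rows = []
    for pid, dx_month in dx_months.items():
        status = classify_patient(pid, claims_by_patient.get(pid, []), dx_month, codeset)
        rows.append(
            {
                "patient_id": pid,
                "a1": status.a1,
                "a2": status.a2,
                "a3": status.a3,
                "a3_expanded": status.a3_expanded,
                "bm_ever": status.bm_ever,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "a1", "a2", "a3", "a3_expanded", "bm_ever"]
    )


def two_step_diagnostic_filter(
    claims: Sequence[Claim],
    codeset: CodeSet = DEFAULT_CODESET,
    lookahead_days: int = DEFAULT_GAP_DAYS,
) -> list[Claim]:
    """Drop diagnostic-category claims not confirmed by a later BM claim.

    Services that merely rule BM out should carry no BM diagnosis code, so a
    diagnostic claim (bone scan, bone/joint imaging, bone biopsy) is kept
    only if some BM-coded claim follows it within ``lookahead_days`` days
    (same-day confirmation counts).  Non-diagnostic claims pass unchanged.
    """
    bm_dates = sorted(c.service_date for c in claims if _has_bm_code(c, codeset))

    def confirmed(date: dt.date) -> bool:
        return any(0 <= (bm - date).days <= lookahead_days for bm in bm_dates)

    return [
        c
        for c in claims
        if c.service_category not in codeset.diagnostic_categories
        or confirmed(c.service_date)
    ]
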