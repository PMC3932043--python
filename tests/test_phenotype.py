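"""Rule-by-rule unit checks plus randomized invariants for the classifiers."""

import datetime as dt

import numpy as np
import pytest

from bonemet.codes import DEFAULT_CODESET, CodeSet
from bonemet.datamodel import Claim
from bonemet.phenotype import (
    Window,
    bm_ever,
    classify_a1,
    classify_a2,
    classify_a3,
    classify_a3_expanded,
    classify_patient,
    two_step_diagnostic_filter,
)

ANCHOR = "2005-06"
W = Window(anchor=ANCHOR)


def claim(date, setting="outpatient", codes=("198.5",), category="other", em=False):
    return Claim("P1", setting, date, tuple(codes), category, em)


class TestApproach1:
    def test_any_position_any_setting(self):
        c = claim("2005-06-10", "carrier", ("185", "V10.46", "401.9", "198.5"))
        assert classify_a1([c], W)

    def test_claim_outside_window_ignored(self):
        assert not classify_a1([claim("2005-08-01")], W)  # anchor+2

    def test_month_before_and_after_count(self):
        assert classify_a1([claim("2005-05-01")], W)
        assert classify_a1([claim("2005-07-31")], W)

    def test_no_claims_is_negative(self):
        assert not classify_a1([], W)


class TestApproach2:
    def test_inpatient_secondary_diagnosis(self):
        assert classify_a2([claim("2005-06-05", "inpatient", ("185", "198.5"))], W)

    def test_inpatient_third_position_fails(self):
        c = claim("2005-06-05", "inpatient", ("185", "401.9", "198.5"))
        assert not classify_a2([c], W)
        assert classify_a1([c], W)  # still generous-rule positive

    def test_outpatient_self_paired(self):
        assert classify_a2([claim("2005-06-05", category="bone_scan")], W)

    def test_outpatient_same_date_procedure_pairing(self):
        bm = claim("2005-06-05")
        scan = claim("2005-06-05", codes=("185",), category="bone_scan")
        assert classify_a2([bm, scan], W)
        # a different-date procedure does not pair
        assert not classify_a2([bm, claim("2005-06-06", codes=("185",), category="bone_scan")], W)

    def test_carrier_requires_em(self):
        assert classify_a2([claim("2005-06-05", "carrier", em=True)], W)
        assert not classify_a2([claim("2005-06-05", "carrier", em=False)], W)


class TestApproach3:
    def test_inpatient_any_position(self):
        codes = tuple(["185"] * 8 + ["198.5"])  # position 9
        assert classify_a3([claim("2005-06-05", "inpatient", codes)], W)

    def test_two_outpatient_within_90_days(self):
        assert classify_a3([claim("2005-05-02"), claim("2005-07-20")], W)  # 79 days

    def test_two_outpatient_91_days_apart_fail(self):
        assert not classify_a3([claim("2005-05-01"), claim("2005-07-31")], W)  # 91 days

    def test_exactly_90_days_counts(self):
        assert classify_a3([claim("2005-05-01"), claim("2005-07-30")], W)

    def test_duplicate_lines_same_date_count_once(self):
        assert not classify_a3([claim("2005-06-05"), claim("2005-06-05")], W)

    def test_single_outpatient_claim_insufficient(self):
        assert not classify_a3([claim("2005-06-05")], W)


class TestExpandedApproach3:
    def test_psa_pair_79_days(self):
        claims = [
            claim("2005-05-02", codes=("185",), category="psa_test"),
            claim("2005-07-20", codes=("185",), category="psa_test"),
        ]
        assert not classify_a3(claims, W)
        assert classify_a3_expanded(claims, W)

    def test_superset_of_base_rule(self):
        claims = [claim("2005-06-05", "inpatient")]
        assert classify_a3(claims, W)
        assert classify_a3_expanded(claims, W)

    def test_mixed_categories_pair(self):
        claims = [
            claim("2005-06-05", codes=("185",), category="psa_test"),
            claim("2005-06-15", codes=("185",), category="bone_joint_imaging"),
        ]
        assert classify_a3_expanded(claims, W)

    def test_same_date_tests_count_once(self):
        claims = [
            claim("2005-06-05", codes=("185",), category="psa_test"),
            claim("2005-06-05", codes=("185",), category="bone_joint_imaging"),
        ]
        assert not classify_a3_expanded(claims, W)


class TestBmEver:
    def test_late_claim_ever_but_not_concurrent(self):
        late = claim("2006-08-10", "inpatient")  # 14 months after anchor
        assert not classify_a3([late], W)
        assert bm_ever([late], ANCHOR)

    def test_claim_before_window_never_counts(self):
        early = claim("2005-03-10", "inpatient")  # anchor-3
        assert not bm_ever([early], ANCHOR)

    def test_concurrent_implies_ever(self):
        claims = [claim("2005-06-05", "inpatient")]
        status = classify_patient("P1", claims, ANCHOR)
        assert status.a3 and status.bm_ever


class TestTwoStepFilter:
    def test_scan_confirmed_within_90_days_kept(self):
        scan = claim("2005-06-01", codes=("185",), category="bone_scan")
        confirm = claim("2005-07-31", "inpatient")  # 60 days later
        assert scan in two_step_diagnostic_filter([scan, confirm])

    def test_scan_confirmed_too_late_dropped(self):
        scan = claim("2005-06-01", codes=("185",), category="bone_scan")
        confirm = claim("2005-09-29", "inpatient")  # 120 days later
        assert scan not in two_step_diagnostic_filter([scan, confirm])

    def test_no_bm_claims_drops_all_diagnostics(self):
        claims = [
            claim("2005-06-01", codes=("185",), category="bone_scan"),
            claim("2005-06-02", codes=("185",), category="bone_joint_imaging"),
            claim("2005-06-03", codes=("185",), category="psa_test"),  # not diagnostic
        ]
        kept = two_step_diagnostic_filter(claims)
        assert [c.service_category for c in kept] == ["psa_test"]

    def test_prior_bm_claim_does_not_confirm(self):
        scan = claim("2005-06-10", codes=("185",), category="bone_scan")
        earlier_bm = claim("2005-06-01", "inpatient")
        assert scan not in two_step_diagnostic_filter([scan, earlier_bm])


# ---------------------------------------------------------------------------
# Randomized invariants


SETTINGS = ("inpatient", "outpatient", "carrier")
CODES = ("198.5", "185", "V10.46", "401.9")
CATEGORIES = ("other", "bone_scan", "psa_test", "bone_joint_imaging", "em_visit")


def random_history(rng: np.random.Generator, n_max: int = 6) -> list[Claim]:
    base = dt.date(2005, 5, 1)
    claims = []
    for _ in range(int(rng.integers(0, n_max + 1))):
        n_codes = int(rng.integers(1, 4))
        codes = tuple(CODES[i] for i in rng.integers(0, len(CODES), n_codes))
        claims.append(
            Claim(
                "P1",
                SETTINGS[int(rng.integers(0, 3))],
                base + dt.timedelta(days=int(rng.integers(0, 120))),
                codes,
                CATEGORIES[int(rng.integers(0, len(CATEGORIES)))],
                bool(rng.integers(0, 2)),
            )
        )
    return claims


def test_nesting_invariants_on_random_histories():
    """a2 => a1, a3 => a1, a3 => expanded, concurrent => ever, everywhere."""
    rng = np.random.default_rng(42)
    for _ in range(2000):
        claims = random_history(rng)
        s = classify_patient("P1", claims, ANCHOR)
        assert not s.a2 or s.a1
        assert not s.a3 or s.a1
        assert not s.a3 or s.a3_expanded
        assert not s.a3 or s.bm_ever


def random_history_day28(rng: np.random.Generator, n_max: int = 6) -> list[Claim]:
    # days capped at 28 so month-shifting claims cannot move a day gap
    # across the 90-day boundary (month lengths differ)
    claims = []
    for _ in range(int(rng.integers(0, n_max + 1))):
        n_codes = int(rng.integers(1, 4))
        codes = tuple(CODES[i] for i in rng.integers(0, len(CODES), n_codes))
        claims.append(
            Claim(
                "P1",
                SETTINGS[int(rng.integers(0, 3))],
                dt.date(2005, int(rng.integers(3, 10)), int(rng.integers(1, 29))),
                codes,
                CATEGORIES[int(rng.integers(0, len(CATEGORIES)))],
                bool(rng.integers(0, 2)),
            )
        )
    return claims


def test_translation_invariance():
    """Shifting every claim and the anchor by the same month count changes nothing."""
    rng = np.random.default_rng(43)
    for _ in range(300):
        claims = random_history_day28(rng)
        shift = int(rng.integers(-24, 25))
        shifted = [
            Claim(
                c.patient_id,
                c.setting,
                _shift_months(c.service_date, shift),
                c.dx_codes,
                c.service_category,
                c.is_physician_em,
            )
            for c in claims
        ]
        original = classify_patient("P1", claims, ANCHOR)
        moved = classify_patient("P1", shifted, Window(ANCHOR).anchor + shift)
        assert (original.a1, original.a2, original.a3, original.a3_expanded) == (
            moved.a1,
            moved.a2,
            moved.a3,
            moved.a3_expanded,
        )


def _shift_months(date: dt.date, k: int) -> dt.date:
    month0 = date.year * 12 + (date.month - 1) + k
    year, month = divmod(month0, 12)
    return dt.date(year, month + 1, min(date.day, 28))


def test_codeset_is_configurable():
    """A variant code set changes what counts as bone-metastasis evidence."""
    alt = CodeSet(bm_dx_codes=frozenset({"198.50"}))
    c = claim("2005-06-05", "inpatient", ("198.5",))
    assert classify_a1([c], W, DEFAULT_CODESET)
    assert not classify_a1([c], W, alt)
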