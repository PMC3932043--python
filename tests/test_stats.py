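"""Concordance statistics: frozen published values, algebraic identities,
and the small-cell suppression contract."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from bonemet.cohort import CohortMember
from bonemet.datamodel import Claim
from bonemet.stats import (
    CrossTab2x2,
    chi_square,
    concordance,
    crosstab,
    mean_compare,
    proportion_ci,
    render_utilization,
    round_half_up,
    sens_spec_ppv,
    utilization_table,
)

A3_CELLS = CrossTab2x2(tp=813, fp=385, fn=881, tn=629)


class TestCrosstab:
    def test_cells_partition_the_cohort(self):
        reg = {"a": True, "b": True, "c": False, "d": False}
        clm = {"a": True, "b": False, "c": True, "d": False}
        ct = crosstab(reg, clm)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (1, 1, 1, 1)

    def test_all_negative_flags(self):
        reg = {k: False for k in "abcd"}
        ct = crosstab(reg, dict(reg))
        assert (ct.tn, ct.tp + ct.fp + ct.fn) == (4, 0)

    def test_perfect_concordance(self):
        reg = {"a": True, "b": False}
        ct = crosstab(reg, dict(reg))
        assert ct.fp == ct.fn == 0

    def test_unmatched_ids_raise(self):
        with pytest.raises(ValueError, match="patient ids"):
            crosstab({"a": True}, {"b": True})


class TestSensSpecPpv:
    def test_approach3_point_estimates(self):
        sens, spec, ppv = sens_spec_ppv(A3_CELLS)
        assert (round_half_up(sens), round_half_up(spec), round_half_up(ppv)) == (
            0.480,
            0.620,
            0.679,
        )

    def test_approach2_ppv(self):
        _, _, ppv = sens_spec_ppv(CrossTab2x2(tp=941, fp=422, fn=753, tn=592))
        assert round_half_up(ppv) == 0.690

    def test_zero_denominator_is_undefined_not_zero(self):
        sens, spec, ppv = sens_spec_ppv(CrossTab2x2(tp=0, fp=0, fn=10, tn=10))
        assert sens == 0.0 and spec == 1.0 and ppv is None

    def test_exact_rational_recovery(self):
        # recomputing sensitivity from the cells is exact, not approximate
        ct = CrossTab2x2(tp=7, fp=2, fn=3, tn=5)
        sens, _, _ = sens_spec_ppv(ct)
        assert sens == ct.tp / (ct.tp + ct.fn)


class TestProportionCI:
    def test_published_sensitivity_bounds(self):
        low, high = proportion_ci(813, 1694, "wald")
        assert (round_half_up(low), round_half_up(high)) == (0.456, 0.504)

    def test_published_specificity_bounds(self):
        low, high = proportion_ci(629, 1014, "wald")
        assert (round_half_up(low), round_half_up(high)) == (0.590, 0.650)

    def test_wald_truncated_at_zero(self):
        low, _ = proportion_ci(0, 50, "wald")
        assert low == 0.0

    def test_wilson_matches_closed_form(self):
        # independent evaluation of the score-interval closed form
        k, n = 813, 1694
        z = sps.norm.ppf(0.975)
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = (z / denom) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        low, high = proportion_ci(k, n, "wilson")
        assert low == pytest.approx(center - half, abs=1e-12)
        assert high == pytest.approx(center + half, abs=1e-12)
        # at this n the Wald and Wilson bounds agree to 3 decimals
        assert [round_half_up(b) for b in proportion_ci(k, n, "wald")] == [
            round_half_up(b) for b in (low, high)
        ]

    def test_interval_contains_point_estimate(self):
        for k, n in [(0, 10), (3, 10), (10, 10), (813, 1694)]:
            for method in ("wald", "wilson"):
                low, high = proportion_ci(k, n, method)
                assert low <= k / n <= high
                assert high - low <= 1.0

    def test_wald_and_wilson_converge_for_large_n(self):
        k, n = 480_000, 1_000_000
        wald = proportion_ci(k, n, "wald")
        wilson = proportion_ci(k, n, "wilson")
        assert wald == pytest.approx(wilson, abs=1e-5)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)


class TestChiSquare:
    def test_hand_computed_statistic(self):
        stat, df, _ = chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(4 * (5**2) / 15)  # all expected cells are 15
        assert df == 1

    def test_proportional_table_is_null(self):
        stat, _, p = chi_square([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bisphosphonate_subgroup_difference(self):
        # within registry-positive patients: IV bisphosphonate use by
        # concurrent-claims status (351/813 vs 242/881)
        _, _, p = chi_square([[351, 813 - 351], [242, 881 - 242]])
        assert p < 0.01

    def test_equals_squared_two_proportion_z(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n1, n2 = rng.integers(20, 200, size=2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            stat, _, _ = chi_square([[k1, n1 - k1], [k2, n2 - k2]])
            pooled = (k1 + k2) / (n1 + n2)
            z = (k1 / n1 - k2 / n2) / math.sqrt(
                pooled * (1 - pooled) * (1 / n1 + 1 / n2)
            )
            assert stat == pytest.approx(z**2, rel=1e-9)

    def test_zero_expected_cell_advises_collapse(self):
        with pytest.raises(ValueError, match="collapse"):
            chi_square([[0, 0], [5, 5]])


class TestMeanCompare:
    def test_identical_groups_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        mx, sdx, my, sdy, p = mean_compare(x, list(x))
        assert mx == my and sdx == sdy
        assert p == pytest.approx(1.0)

    def test_large_shift_small_p(self):
        _, _, _, _, p = mean_compare([0.0, 0.1], [100.0, 100.1])
        assert p < 0.01

    def test_singleton_group_flags_undefined(self):
        _, sdx, _, _, p = mean_compare([1.0], [1.0, 2.0])
        assert sdx is None and p is None

    def test_type_i_error_near_nominal(self):
        # simulation oracle: equal-mean normals should reject ~5% of the time
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 800
        for _ in range(reps):
            x = rng.normal(size=25)
            y = rng.normal(size=40)
            *_, p = mean_compare(x, y)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


def _member(pid, dx="2005-06"):
    return CohortMember(pid, dx_month=__import__("pandas").Period(dx, freq="M"),
                        censor_month=__import__("pandas").Period("2009-12", freq="M"),
                        registry_bm=False)


def _psa(pid, date):
    return Claim(pid, "outpatient", date, ("185",), "psa_test")


def make_utilization_inputs(n_a=20, n_b=20, users_a=15, users_b=4):
    """Two strata of patients, the first ``users_*`` of each with one
    post-diagnosis PSA claim."""
    cohort = [_member(f"A{i}") for i in range(n_a)] + [
        _member(f"B{i}") for i in range(n_b)
    ]
    strata = {m.patient_id: m.patient_id[0] for m in cohort}
    claims = {}
    for i in range(users_a):
        claims[f"A{i}"] = [_psa(f"A{i}", "2005-09-15")]
    for i in range(users_b):
        claims[f"B{i}"] = [_psa(f"B{i}", "2005-09-15")]
    return cohort, claims, strata


class TestUtilizationTable:
    def test_counts_and_percentages(self):
        cohort, claims, strata = make_utilization_inputs()
        (row,) = utilization_table(cohort, claims, strata, ["psa_test"], "post")
        assert row.stratum_n == (20, 20)
        assert row.users == (15, 4)
        assert row.pct == (75.0, 20.0)

    def test_window_period_excludes_later_claims(self):
        cohort, claims, strata = make_utilization_inputs()
        (row,) = utilization_table(cohort, claims, strata, ["psa_test"], "window")
        assert row.users == (0, 0)  # claims are 3 months after diagnosis

    def test_small_cell_marked_and_rendered_nr(self):
        cohort, claims, strata = make_utilization_inputs(users_b=7)
        rows = utilization_table(cohort, claims, strata, ["psa_test"], "post")
        assert rows[0].suppressed
        frame = render_utilization(rows, ["A", "B"])
        assert frame.loc[0, "B_n"] == "NR"
        assert frame.loc[0, "B_pct"] == "NR"
        assert frame.loc[0, "A_n"] == 15  # large cell still reported

    def test_zero_users_reportable_not_suppressed(self):
        cohort, claims, strata = make_utilization_inputs(users_a=0, users_b=0)
        rows = utilization_table(cohort, claims, strata, ["psa_test"], "post")
        assert not rows[0].suppressed
        frame = render_utilization(rows, ["A", "B"])
        assert frame.loc[0, "A_n"] == 0 and frame.loc[0, "A_pct"] == 0.0

    def test_no_rendered_cell_in_suppression_band(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cohort, claims, strata = make_utilization_inputs(
                users_a=int(rng.integers(0, 21)), users_b=int(rng.integers(0, 21))
            )
            rows = utilization_table(cohort, claims, strata, ["psa_test"], "post")
            frame = render_utilization(rows, ["A", "B"])
            for col in ("A_n", "B_n"):
                value = frame.loc[0, col]
                if value != "NR":
                    assert not (0 < int(value) < 11)

    def test_unknown_stratum_label_raises(self):
        cohort, claims, strata = make_utilization_inputs()
        del strata["A0"]
        with pytest.raises(ValueError, match="stratum"):
            utilization_table(cohort, claims, strata, ["psa_test"], "post")


def test_concordance_bundle_is_consistent():
    result = concordance(A3_CELLS, ci_method="wald")
    assert result.sensitivity_ci[0] <= result.sensitivity <= result.sensitivity_ci[1]
    assert result.n_pos == 1694 and result.n_neg == 1014 and result.n_flagged == 1198
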