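"""Seeded synthetic registry + claims + enrollment generator.

The real study data (a linked cancer-registry / Medicare-claims cohort) are
access-restricted, so this module builds a synthetic stand-in with the same
structure: eligible patients plus ineligible decoys, with claim histories
*engineered* so that the downstream pipeline lands each patient in a
prescribed cell of every classification rule's 2x2 table simultaneously.

Calibration works backwards from published statistics.  ``derive_crosstab``
performs an exhaustive integer search for the unique cell assignment
(tp, fp, fn, tn) whose sensitivity, specificity and PPV all round (half-up,
3 decimals) to the printed values given the printed margins; the expanded-
rule numerators are recovered the same way, using the printed confidence
intervals to break rounding ties.  ``generate_fixture`` then emits one
claim recipe per patient:

* ``inpatient_bm`` — inpatient claim, BM code in a configurable diagnosis
  position (primary by default): positive under Approaches 1, 2 and 3;
* ``carrier_em_bm`` — single carrier E&M claim with the BM code: positive
  under Approaches 1 and 2 only;
* ``outpatient_unpaired_bm`` — single outpatient BM-coded claim with no
  paired procedure: positive under Approach 1 only;
* ``none`` — no BM-coded claim in the window: negative everywhere.

This recipe ladder realises the nested joint structure A3+ ⊆ A2+ ⊆ A1+,
the unique maximal-overlap structure consistent with the published marginal
counts (the publication reports no joint distribution).  Expanded-rule
positives additionally receive two outpatient test claims (PSA / bone-joint
imaging) on distinct dates within 90 days inside the window.

Utilization noise (service categories drawn Bernoulli per stratum) is
placed so it can never flip an engineered status: claims after the window
carry no BM code, and all in-window utilization claims for a patient share
one service date distinct from the recipe dates — the expanded rule needs
two distinct dates, and Approach-2 pairing needs same-date co-occurrence
with a BM-coded claim.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codes import DEFAULT_CODESET, CodeSet
from .datamodel import Claim, EnrollmentSpan, RegistryRecord
from .errors import CrosstabAmbiguityError, CrosstabInconsistencyError, SpecConsistencyError
from .io import write_tables
from .stats import proportion_ci, ratio_rounds_to, round_half_up
from .timeutil import parse_month

APPROACHES = ("a1", "a2", "a3")
RECIPES = ("inpatient_bm", "carrier_em_bm", "outpatient_unpaired_bm", "none")

#: Published marginal inputs: per approach, the three printed statistics
#: (3 dp) and the number of claims-flagged patients; plus total and
#: registry-positive counts.
PRINTED_TOTAL = 2708
PRINTED_REGISTRY_BM = 1694
PRINTED_STATS = {
    "a1": {"sens": "0.598", "spec": "0.538", "ppv": "0.684", "n_flagged": 1481},
    "a2": {"sens": "0.555", "spec": "0.584", "ppv": "0.690", "n_flagged": 1363},
    "a3": {"sens": "0.480", "spec": "0.620", "ppv": "0.679", "n_flagged": 1198},
}
PRINTED_EXPANDED = {
    "sens": "0.581",
    "sens_ci": ("0.558", "0.605"),
    "spec": "0.558",
    "spec_ci": ("0.527", "0.589"),
}

PCA_DX_CODE = "185"  # ICD-9 malignant neoplasm of prostate (benign filler code)

RACES = ("white_nh", "black_nh", "hispanic", "other")
RACE_PROBS = (0.774, 0.120, 0.059, 0.047)
COMORBIDITY = ("0", "1", "2+", "missing")
COMORBIDITY_PROBS = (0.537, 0.202, 0.173, 0.088)

#: Any-use Bernoulli probabilities per (period, category) and stratum.
#: Registry-positive strata follow the published within-M1b columns by
#: Approach-3 status; registry-negative patients follow the published
#: no-registry-BM column (the joint breakdown is not published).
DEFAULT_UTILIZATION_PROBS: dict[tuple[str, str], dict[str, float]] = {
    ("post", "bmd_test"): {"bm_pos_a3pos": 0.035, "bm_pos_a3neg": 0.049, "bm_neg": 0.038},
    ("post", "psa_test"): {"bm_pos_a3pos": 0.787, "bm_pos_a3neg": 0.850, "bm_neg": 0.749},
    ("post", "oncologist_visit"): {"bm_pos_a3pos": 0.697, "bm_pos_a3neg": 0.538, "bm_neg": 0.631},
    ("post", "bone_biopsy"): {"bm_pos_a3pos": 0.052, "bm_pos_a3neg": 0.011, "bm_neg": 0.032},
    ("post", "bone_joint_imaging"): {"bm_pos_a3pos": 0.841, "bm_pos_a3neg": 0.820, "bm_neg": 0.783},
    ("post", "radiation"): {"bm_pos_a3pos": 0.388, "bm_pos_a3neg": 0.302, "bm_neg": 0.304},
    ("post", "radiopharmaceutical"): {"bm_pos_a3pos": 0.055, "bm_pos_a3neg": 0.031, "bm_neg": 0.019},
    ("post", "iv_bisphosphonate"): {"bm_pos_a3pos": 0.432, "bm_pos_a3neg": 0.275, "bm_neg": 0.265},
    ("window", "psa_test"): {"bm_pos_a3pos": 0.592, "bm_pos_a3neg": 0.641, "bm_neg": 0.575},
    ("window", "bone_joint_imaging"): {"bm_pos_a3pos": 0.849, "bm_pos_a3neg": 0.712, "bm_neg": 0.682},
    ("window", "bone_biopsy"): {"bm_pos_a3pos": 0.05, "bm_pos_a3neg": 0.01, "bm_neg": 0.023},
}

DEFAULT_DECOYS = {
    "age_under_66": 50,
    "hmo_in_baseline": 50,
    "gap_in_AB": 50,
    "prior_cancer": 50,
    "non_M1": 50,
}


# ---------------------------------------------------------------------------
# Calibration: integer consistency search over printed statistics


@dataclass(frozen=True)
class CrossTabSpec:
    """Prescribed 2x2 cells for one classification rule."""

    approach: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise SpecConsistencyError("cross-tab cells must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp


def derive_crosstab(
    approach: str,
    printed_sens: str | Decimal,
    printed_spec: str | Decimal,
    printed_ppv: str | Decimal,
    n_pos: int,
    n_flagged: int,
    n_total: int = PRINTED_TOTAL,
) -> CrossTabSpec:
    """Recover the unique integer 2x2 cells behind printed 3-dp statistics.

    Searches tp over [0, n_pos] with fp = n_flagged - tp and requires that
    tp/n_pos, tn/n_neg and tp/n_flagged all round (half-up) to the printed
    sensitivity, specificity and PPV.  Raises if no assignment or more than
    one assignment satisfies all three constraints.
    """
    n_neg = n_total - n_pos
    solutions = []
    for tp in range(0, n_pos + 1):
        fp = n_flagged - tp
        if not 0 <= fp <= n_neg:
            continue
        tn = n_neg - fp
        if (
            ratio_rounds_to(tp, n_pos, printed_sens)
            and ratio_rounds_to(tn, n_neg, printed_spec)
            and ratio_rounds_to(tp, n_flagged, printed_ppv)
        ):
            solutions.append(CrossTabSpec(approach, tp, fp, n_pos - tp, tn))
    if not solutions:
        raise CrosstabInconsistencyError(
            f"{approach}: no integer cells reproduce "
            f"({printed_sens}, {printed_spec}, {printed_ppv}) "
            f"with n_pos={n_pos}, n_flagged={n_flagged}, n_total={n_total}"
        )
    if len(solutions) > 1:
        raise CrosstabAmbiguityError(
            f"{approach}: {len(solutions)} cell assignments fit", candidates=solutions
        )
    return solutions[0]


def _unique_numerator(
    printed: str, printed_ci: tuple[str, str], n: int, ci_method: str = "wald"
) -> int:
    """Unique k in [0, n] with k/n rounding to the printed value; rounding
    ties are broken by closeness of the Wald CI bounds to the printed CI."""
    candidates = [k for k in range(n + 1) if ratio_rounds_to(k, n, printed)]
    if not candidates:
        raise CrosstabInconsistencyError(f"no numerator of /{n} rounds to {printed}")
    if len(candidates) == 1:
        return candidates[0]
    lo_p, hi_p = (float(Decimal(b)) for b in printed_ci)

    def ci_deviation(k: int) -> float:
        lo, hi = proportion_ci(k, n, method=ci_method)
        return abs(round_half_up(lo, 3) - lo_p) + abs(round_half_up(hi, 3) - hi_p)

    best = min(candidates, key=ci_deviation)
    deviations = sorted(ci_deviation(k) for k in candidates)
    if deviations[0] == deviations[1]:
        raise CrosstabAmbiguityError(
            f"numerators {candidates} equally consistent with CI {printed_ci}",
            candidates=candidates,
        )
    return best


def derive_expanded_extras(
    base_a3: CrossTabSpec,
    printed: dict = PRINTED_EXPANDED,
) -> tuple[int, int]:
    """(extra true positives, extra false positives) for the expanded rule.

    The expanded rule is a superset of Approach 3, so its tp and fp can only
    grow; the printed expanded sensitivity/specificity (with their CIs for
    tie-breaking) pin down the new numerators uniquely.
    """
    tp_x = _unique_numerator(printed["sens"], printed["sens_ci"], base_a3.n_pos)
    tn_x = _unique_numerator(printed["spec"], printed["spec_ci"], base_a3.n_neg)
    fp_x = base_a3.n_neg - tn_x
    if tp_x < base_a3.tp or fp_x < base_a3.fp:
        raise SpecConsistencyError(
            "expanded rule cells shrink below the base Approach-3 cells"
        )
    return tp_x - base_a3.tp, fp_x - base_a3.fp


# ---------------------------------------------------------------------------
# Fixture specification


@dataclass
class FixtureSpec:
    """Everything the generator needs, with published-study defaults."""

    crosstabs: dict[str, CrossTabSpec]
    n_total: int = PRINTED_TOTAL
    n_registry_bm: int = PRINTED_REGISTRY_BM
    n_expanded_extra_tp: int = 0
    n_expanded_extra_fp: int = 0
    n_decoys_by_reason: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DECOYS)
    )
    utilization_probs: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: {
            key: dict(value) for key, value in DEFAULT_UTILIZATION_PROBS.items()
        }
    )
    late_bm_ever_prob: float = 0.1
    dx_years: tuple[int, int] = (2005, 2007)
    study_end: str = "2009-12"
    inpatient_bm_position: int = 1
    seed: int = 20140102

    def validate(self) -> None:
        n_neg = self.n_total - self.n_registry_bm
        if n_neg < 0:
            raise SpecConsistencyError("n_registry_bm exceeds n_total")
        for name in APPROACHES:
            if name not in self.crosstabs:
                raise SpecConsistencyError(f"missing cross-tab for {name}")
            ct = self.crosstabs[name]
            if ct.tp + ct.fn != self.n_registry_bm or ct.fp + ct.tn != n_neg:
                raise SpecConsistencyError(
                    f"{name}: cells do not sum to the registry margins"
                )
        a1, a2, a3 = (self.crosstabs[k] for k in APPROACHES)
        if not (a3.tp <= a2.tp <= a1.tp and a3.fp <= a2.fp <= a1.fp):
            raise SpecConsistencyError(
                "nested joint structure requires A3 cells <= A2 cells <= A1 cells"
            )
        if self.n_expanded_extra_tp > self.n_registry_bm - a3.tp:
            raise SpecConsistencyError("more expanded extra TPs than A3-negative positives")
        if self.n_expanded_extra_fp > n_neg - a3.fp:
            raise SpecConsistencyError("more expanded extra FPs than A3-negative negatives")
        if any(n < 0 for n in self.n_decoys_by_reason.values()):
            raise SpecConsistencyError("decoy counts must be non-negative")
        for key, by_stratum in self.utilization_probs.items():
            for stratum, p in by_stratum.items():
                if not 0.0 <= p <= 1.0:
                    raise SpecConsistencyError(
                        f"utilization probability out of [0,1] for {key}/{stratum}"
                    )
        if not 0.0 <= self.late_bm_ever_prob <= 1.0:
            raise SpecConsistencyError("late_bm_ever_prob out of [0,1]")
        if not 1 <= self.inpatient_bm_position:
            raise SpecConsistencyError("inpatient_bm_position must be >= 1")

    def expanded_crosstab(self) -> CrossTabSpec:
        a3 = self.crosstabs["a3"]
        return CrossTabSpec(
            "a3_expanded",
            tp=a3.tp + self.n_expanded_extra_tp,
            fp=a3.fp + self.n_expanded_extra_fp,
            fn=a3.fn - self.n_expanded_extra_tp,
            tn=a3.tn - self.n_expanded_extra_fp,
        )


def canonical_spec(seed: int = 20140102) -> FixtureSpec:
    """The study-condition fixture: cells recovered from the printed tables."""
    crosstabs = {
        name: derive_crosstab(
            name,
            stats["sens"],
            stats["spec"],
            stats["ppv"],
            n_pos=PRINTED_REGISTRY_BM,
            n_flagged=stats["n_flagged"],
            n_total=PRINTED_TOTAL,
        )
        for name, stats in PRINTED_STATS.items()
    }
    extra_tp, extra_fp = derive_expanded_extras(crosstabs["a3"])
    spec = FixtureSpec(
        crosstabs=crosstabs,
        n_expanded_extra_tp=extra_tp,
        n_expanded_extra_fp=extra_fp,
        seed=seed,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Templates and claim emission


@dataclass(frozen=True)
class PatientTemplate:
    """Designated status of one eligible patient under every rule."""

    registry_bm: bool
    recipe: str
    expanded_tests: bool = False  # two in-window PSA/imaging claims added

    def __post_init__(self):
        if self.recipe not in RECIPES:
            raise SpecConsistencyError(f"unknown recipe {self.recipe!r}")

    @property
    def a1_pos(self) -> bool:
        return self.recipe != "none"

    @property
    def a2_pos(self) -> bool:
        return self.recipe in ("inpatient_bm", "carrier_em_bm")

    @property
    def a3_pos(self) -> bool:
        return self.recipe == "inpatient_bm"

    @property
    def expanded_pos(self) -> bool:
        return self.a3_pos or self.expanded_tests


def build_templates(spec: FixtureSpec) -> list[PatientTemplate]:
    """Expand the cross-tab cells into one template per eligible patient."""
    spec.validate()
    a1, a2, a3 = (spec.crosstabs[k] for k in APPROACHES)
    templates: list[PatientTemplate] = []
    for registry_bm, n_arm, k3, k2, k1, extras in (
        (True, spec.n_registry_bm, a3.tp, a2.tp, a1.tp, spec.n_expanded_extra_tp),
        (False, spec.n_total - spec.n_registry_bm, a3.fp, a2.fp, a1.fp, spec.n_expanded_extra_fp),
    ):
        ladder = (
            ["inpatient_bm"] * k3
            + ["carrier_em_bm"] * (k2 - k3)
            + ["outpatient_unpaired_bm"] * (k1 - k2)
            + ["none"] * (n_arm - k1)
        )
        # expanded extras must be base-A3-negative; take them from the
        # all-negative tail so the recipes stay maximally simple
        n_none = n_arm - k1
        if extras > n_none:
            raise SpecConsistencyError(
                "expanded extras exceed the all-negative group; "
                "reduce extras or loosen the nesting"
            )
        flags = [False] * (len(ladder) - extras) + [True] * extras
        templates.extend(
            PatientTemplate(registry_bm=registry_bm, recipe=r, expanded_tests=f)
            for r, f in zip(ladder, flags)
        )
    return templates


@dataclass
class Fixture:
    """In-memory fixture: raw tables plus the generating templates."""

    registry: list[RegistryRecord]
    claims: list[Claim]
    enrollment: list[EnrollmentSpan]
    templates: dict[str, PatientTemplate]


def _day(month: pd.Period, day: int):
    return month.to_timestamp().to_pydatetime().date().replace(day=day)


def _recipe_claims(
    pid: str, dx_month: pd.Period, template: PatientTemplate, bm_code: str, position: int
) -> list[Claim]:
    claims = []
    if template.recipe == "inpatient_bm":
        codes = [PCA_DX_CODE] * (position - 1) + [bm_code]
        claims.append(
            Claim(pid, "inpatient", _day(dx_month, 5), tuple(codes), "other")
        )
    elif template.recipe == "carrier_em_bm":
        claims.append(
            Claim(
                pid,
                "carrier",
                _day(dx_month, 7),
                (bm_code, PCA_DX_CODE),
                "em_visit",
                is_physician_em=True,
            )
        )
    elif template.recipe == "outpatient_unpaired_bm":
        claims.append(
            Claim(pid, "outpatient", _day(dx_month, 9), (PCA_DX_CODE, bm_code), "other")
        )
    if template.expanded_tests:
        claims.append(
            Claim(pid, "outpatient", _day(dx_month, 6), (PCA_DX_CODE,), "psa_test")
        )
        claims.append(
            Claim(
                pid,
                "outpatient",
                _day(dx_month, 26),
                (PCA_DX_CODE,),
                "bone_joint_imaging",
            )
        )
    return claims


def _utilization_claims(
    pid: str,
    dx_month: pd.Period,
    stratum: str,
    probs: dict[tuple[str, str], dict[str, float]],
    rng: np.random.Generator,
) -> list[Claim]:
    claims = []
    for (period, category), by_stratum in probs.items():
        p = by_stratum.get(stratum, 0.0)
        if p <= 0.0 or rng.random() >= p:
            continue
        if period == "window":
            # single shared in-window date: utilization noise can never
            # supply the two distinct dates the expanded rule requires
            claims.append(
                Claim(pid, "outpatient", _day(dx_month, 20), (PCA_DX_CODE,), category)
            )
        else:
            n_claims = 1 + int(rng.poisson(6)) if category == "psa_test" else 1
            for _ in range(n_claims):
                month = dx_month + int(rng.integers(2, 25))
                setting = "carrier" if category == "oncologist_visit" else "outpatient"
                claims.append(
                    Claim(
                        pid,
                        setting,
                        _day(month, 15),
                        (PCA_DX_CODE,),
                        category,
                        is_physician_em=(category == "oncologist_visit"),
                    )
                )
    return claims


def _enrollment_rows(
    pid: str,
    dx_month: pd.Period,
    study_end: pd.Period,
    hmo_months: frozenset[int] = frozenset(),
    no_b_months: frozenset[int] = frozenset(),
) -> list[EnrollmentSpan]:
    months = pd.period_range(dx_month - 12, study_end, freq="M")
    return [
        EnrollmentSpan(
            pid,
            m,
            part_a=True,
            part_b=m.ordinal not in no_b_months,
            hmo=m.ordinal in hmo_months,
        )
        for m in months
    ]


def _registry_record(
    pid: str,
    dx_month: pd.Period,
    ajcc_m: str,
    rng: np.random.Generator,
    age: int | None = None,
    prior_cancer: bool = False,
) -> RegistryRecord:
    return RegistryRecord(
        patient_id=pid,
        dx_month=dx_month,
        ajcc_m=ajcc_m,
        age_at_dx=int(rng.integers(66, 95)) if age is None else age,
        sex="male",
        race=str(rng.choice(RACES, p=RACE_PROBS)),
        prior_cancer_within_5y=prior_cancer,
        comorbidity_class=str(rng.choice(COMORBIDITY, p=COMORBIDITY_PROBS)),
    )


def generate_fixture(spec: FixtureSpec, out_dir: str | Path | None = None) -> Fixture:
    """Emit the synthetic raw tables; deterministic for a fixed spec seed.

    Raises before writing anything if the spec is internally inconsistent.
    """
    spec.validate()
    templates = build_templates(spec)
    rng = np.random.default_rng(spec.seed)
    study_end = parse_month(spec.study_end)
    bm_code = sorted(DEFAULT_CODESET.bm_dx_codes)[0]

    order = rng.permutation(len(templates))
    first_dx = pd.Period(f"{spec.dx_years[0]}-01", freq="M")
    n_dx_months = 12 * (spec.dx_years[1] - spec.dx_years[0] + 1)

    registry: list[RegistryRecord] = []
    claims: list[Claim] = []
    enrollment: list[EnrollmentSpan] = []
    by_pid: dict[str, PatientTemplate] = {}

    for serial, template_idx in enumerate(order, start=1):
        template = templates[template_idx]
        pid = f"P{serial:06d}"
        by_pid[pid] = template
        dx_month = first_dx + int(rng.integers(0, n_dx_months))
        registry.append(_registry_record(pid, dx_month, "M1b" if template.registry_bm else ("M1a" if serial % 2 else "M1c"), rng))
        enrollment.extend(_enrollment_rows(pid, dx_month, study_end))
        claims.extend(
            _recipe_claims(pid, dx_month, template, bm_code, spec.inpatient_bm_position)
        )
        if (
            template.registry_bm
            and template.recipe == "none"
            and not template.expanded_tests
            and rng.random() < spec.late_bm_ever_prob
        ):
            # BM-coded claim well after the window: "ever" positive only
            claims.append(
                Claim(pid, "inpatient", _day(dx_month + 6, 12), (bm_code,), "other")
            )
        stratum = (
            "bm_pos_a3pos"
            if template.registry_bm and template.a3_pos
            else "bm_pos_a3neg"
            if template.registry_bm
            else "bm_neg"
        )
        claims.extend(
            _utilization_claims(pid, dx_month, stratum, spec.utilization_probs, rng)
        )

    serial = len(templates)
    for reason, count in spec.n_decoys_by_reason.items():
        for _ in range(count):
            serial += 1
            pid = f"P{serial:06d}"
            dx_month = first_dx + int(rng.integers(0, n_dx_months))
            hmo_months: frozenset[int] = frozenset()
            no_b: frozenset[int] = frozenset()
            age, stage, prior = None, "M1b", False
            if reason == "age_under_66":
                age = 64
            elif reason == "hmo_in_baseline":
                hmo_months = frozenset({dx_month.ordinal - 3})
            elif reason == "gap_in_AB":
                no_b = frozenset({dx_month.ordinal - 5})
            elif reason == "prior_cancer":
                prior = True
            elif reason == "non_M1":
                stage = "M0"
            else:
                raise SpecConsistencyError(f"unknown decoy reason {reason!r}")
            registry.append(
                _registry_record(pid, dx_month, stage, rng, age=age, prior_cancer=prior)
            )
            enrollment.extend(
                _enrollment_rows(pid, dx_month, study_end, hmo_months, no_b)
            )

    fixture = Fixture(registry=registry, claims=claims, enrollment=enrollment, templates=by_pid)
    if out_dir is not None:
        write_tables(registry, claims, enrollment, out_dir)
    return fixture


# ---------------------------------------------------------------------------
# Independent template oracle (deliberately re-implements the rules with
# plain scans; used to cross-check the generator against the classifiers)


def template_oracle(
    template: PatientTemplate,
    claims: Sequence[Claim],
    dx_month: str | pd.Period,
    codeset: CodeSet = DEFAULT_CODESET,
) -> dict[str, bool]:
    """Re-derive each rule's status for one patient by direct scanning.

    Independent of :mod:`bonemet.phenotype`: every rule is re-stated here as
    a straightforward loop so generator bugs and classifier bugs cannot
    cancel out.
    """
    anchor = parse_month(dx_month).ordinal
    bm = codeset.bm_dx_codes

    def in_window(c: Claim) -> bool:
        ordinal = pd.Period(c.service_date, freq="M").ordinal
        return anchor - 1 <= ordinal <= anchor + 1

    window_claims = [c for c in claims if in_window(c)]

    a1 = False
    for c in window_claims:
        for code in c.dx_codes:
            if code in bm:
                a1 = True

    a2 = False
    for c in window_claims:
        if c.setting == "inpatient" and any(code in bm for code in c.dx_codes[:2]):
            a2 = True
        if c.setting == "carrier" and c.is_physician_em and any(
            code in bm for code in c.dx_codes
        ):
            a2 = True
        if c.setting == "outpatient" and any(code in bm for code in c.dx_codes):
            if c.service_category in codeset.pairing_categories:
                a2 = True
            for other in window_claims:
                if (
                    other.setting == "outpatient"
                    and other.service_date == c.service_date
                    and other.service_category in codeset.pairing_categories
                ):
                    a2 = True

    a3 = False
    for c in window_claims:
        if c.setting == "inpatient" and any(code in bm for code in c.dx_codes):
            a3 = True
    bm_out_dates = sorted(
        {
            c.service_date
            for c in window_claims
            if c.setting == "outpatient" and any(code in bm for code in c.dx_codes)
        }
    )
    for d1, d2 in itertools.combinations(bm_out_dates, 2):
        if abs((d2 - d1).days) <= 90:
            a3 = True

    expanded = a3
    test_dates = sorted(
        {
            c.service_date
            for c in window_claims
            if c.setting == "outpatient"
            and c.service_category in codeset.expanded_categories
        }
    )
    for d1, d2 in itertools.combinations(test_dates, 2):
        if abs((d2 - d1).days) <= 90:
            expanded = True

    return {"a1": a1, "a2": a2, "a3": a3, "a3_expanded": expanded}


# ---------------------------------------------------------------------------
# Probabilistic mode (parameter recovery)


def simulate_probabilistic(
    n_pos: int,
    n_neg: int,
    sensitivity: float,
    specificity: float,
    rng: np.random.Generator,
    dx_month: str = "2006-06",
) -> tuple[dict[str, bool], dict[str, list[Claim]], dict[str, pd.Period]]:
    """Draw claim-flag statuses i.i.d. instead of engineering exact cells.

    Each registry-positive patient receives a qualifying inpatient BM claim
    with probability ``sensitivity``; each registry-negative patient with
    probability ``1 - specificity``.  Returns (registry flags, claims by
    patient, diagnosis months) ready for classification.
    """
    dx = parse_month(dx_month)
    bm_code = sorted(DEFAULT_CODESET.bm_dx_codes)[0]
    registry_flags: dict[str, bool] = {}
    claims_by_patient: dict[str, list[Claim]] = {}
    dx_months: dict[str, pd.Period] = {}
    for i in range(n_pos + n_neg):
        pid = f"S{i:05d}"
        positive = i < n_pos
        registry_flags[pid] = positive
        dx_months[pid] = dx
        p_flag = sensitivity if positive else 1.0 - specificity
        claims_by_patient[pid] = (
            [Claim(pid, "inpatient", _day(dx, 5), (bm_code,), "other")]
            if rng.random() < p_flag
            else []
        )
    return registry_flags, claims_by_patient, dx_months
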