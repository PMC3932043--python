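"""Concordance and utilization statistics.

The claims-based flags are cross-tabulated against the registry M1b flag in
a 2x2 table (TP = both positive, FP = claims only, FN = registry only,
TN = neither).  Sensitivity is tp/(tp+fn), specificity tn/(fp+tn), and
positive predictive value tp/(tp+fp); 95% confidence intervals come from
the Wald (normal approximation) or Wilson score construction, truncated to
[0, 1].  Subgroup utilization comparisons use Pearson's chi-square without
continuity correction for any-use proportions and Welch's t-test for count
intensities.  Published-table renderings apply a small-cell suppression rule
(counts between 1 and threshold-1 shown as "NR").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .datamodel import Claim
from .phenotype import Window

SUPPRESSION_THRESHOLD = 11  # counts 1..10 are never shown in rendered tables


def round_half_up(value: float | Decimal, ndigits: int = 3) -> float:
    """Round half away from zero at ``ndigits`` decimals (display rounding)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def ratio_rounds_to(num: int, den: int, printed: str | Decimal) -> bool:
    """Does num/den round (half-up) to the printed decimal exactly?"""
    printed = Decimal(str(printed))
    quantum = Decimal(1).scaleb(printed.as_tuple().exponent)
    value = (Decimal(num) / Decimal(den)).quantize(quantum, rounding=ROUND_HALF_UP)
    return value == printed


@dataclass(frozen=True)
class CrossTab2x2:
    """Claims flag vs registry flag contingency cells."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cross-tab cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Registry-positive margin."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n_flagged(self) -> int:
        """Claims-positive margin."""
        return self.tp + self.fp


@dataclass(frozen=True)
class ConcordanceResult:
    """Point estimates with CI bounds; None marks an undefined statistic."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None
    ci_method: str
    n_pos: int
    n_neg: int
    n_flagged: int


def crosstab(
    registry_flags: Mapping[str, bool], claims_flags: Mapping[str, bool]
) -> CrossTab2x2:
    """Cross-tabulate two per-patient flag mappings aligned on patient id."""
    unmatched = set(registry_flags) ^ set(claims_flags)
    if unmatched:
        raise ValueError(
            "flag mappings disagree on patient ids: "
            + ", ".join(sorted(unmatched)[:10])
            + ("..." if len(unmatched) > 10 else "")
        )
    tp = fp = fn = tn = 0
    for pid, reg in registry_flags.items():
        clm = claims_flags[pid]
        if reg and clm:
            tp += 1
        elif clm:
            fp += 1
        elif reg:
            fn += 1
        else:
            tn += 1
    return CrossTab2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def sens_spec_ppv(
    ct: CrossTab2x2,
) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, PPV); a zero denominator yields None."""
    sens = ct.tp / ct.n_pos if ct.n_pos else None
    spec = ct.tn / ct.n_neg if ct.n_neg else None
    ppv = ct.tp / ct.n_flagged if ct.n_flagged else None
    return sens, spec, ppv


def proportion_ci(
    k: int, n: int, method: str = "wald", level: float = 0.95
) -> tuple[float, float]:
    """Binomial proportion CI (Wald or Wilson score), truncated to [0, 1]."""
    if n <= 0:
        raise ValueError("proportion CI requires n > 0")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    low, high = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    # truncate to [0,1] and absorb float error so the interval always
    # contains the point estimate (Wilson at k=n can return 1 - 1e-16)
    p_hat = k / n
    return min(max(0.0, float(low)), p_hat), max(min(1.0, float(high)), p_hat)


def concordance(
    ct: CrossTab2x2, ci_method: str = "wald", level: float = 0.95
) -> ConcordanceResult:
    sens, spec, ppv = sens_spec_ppv(ct)
    return ConcordanceResult(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        sensitivity_ci=proportion_ci(ct.tp, ct.n_pos, ci_method, level)
        if sens is not None
        else None,
        specificity_ci=proportion_ci(ct.tn, ct.n_neg, ci_method, level)
        if spec is not None
        else None,
        ppv_ci=proportion_ci(ct.tp, ct.n_flagged, ci_method, level)
        if ppv is not None
        else None,
        ci_method=ci_method,
        n_pos=ct.n_pos,
        n_neg=ct.n_neg,
        n_flagged=ct.n_flagged,
    )


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on an r x c table."""
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.min() < 0:
        raise ValueError("need a non-negative 2-D count table")
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if total <= 0 or (row * col / max(total, 1)).min() <= 0:
        raise ValueError(
            "zero expected cell; collapse sparse rows/columns before testing"
        )
    stat, p, dof, _ = sps.chi2_contingency(observed, correction=False)
    return float(stat), int(dof), float(p)


def mean_compare(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float | None, float, float | None, float | None]:
    """Group means, sample SDs (n-1), and the two-sided Welch t-test p.

    SD and p are None when a group is too small for them to be defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    sd_x = float(x.std(ddof=1)) if x.size >= 2 else None
    sd_y = float(y.std(ddof=1)) if y.size >= 2 else None
    if sd_x is None or sd_y is None:
        p = None
    elif sd_x == 0.0 and sd_y == 0.0:
        p = 1.0 if float(x.mean()) == float(y.mean()) else 0.0
    else:
        p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    return float(x.mean()), sd_x, float(y.mean()), sd_y, p


# ---------------------------------------------------------------------------
# Stratified utilization tables


@dataclass(frozen=True)
class UtilizationRow:
    """One service category in one observation period, across strata."""

    category: str
    period: str  # "post" (diagnosis to censor) or "window" (90-day dx period)
    stratum_n: tuple[int, ...]  # patients in each stratum (denominators)
    users: tuple[int, ...]  # patients with any use, per stratum
    pct: tuple[float, ...]  # column percentages (1 dp)
    mean: tuple[float, ...]  # mean claims per patient, per stratum
    sd: tuple[float | None, ...]
    p_any_use: float | None
    p_mean: float | None
    suppressed: bool


def _claims_in_period(
    claims: Sequence[Claim], dx_month, censor_month, period: str
) -> list[Claim]:
    if period == "window":
        window = Window(anchor=dx_month)
        return [c for c in claims if window.contains(c.service_date)]
    if period == "post":
        lo, hi = dx_month.ordinal, censor_month.ordinal
        return [
            c
            for c in claims
            if lo <= pd.Period(c.service_date, freq="M").ordinal <= hi
        ]
    raise ValueError(f"unknown period {period!r}")


def utilization_table(
    cohort,
    claims_by_patient: Mapping[str, Sequence[Claim]],
    strata: Mapping[str, str],
    categories: Sequence[str],
    period: str = "post",
    suppression_threshold: int = SUPPRESSION_THRESHOLD,
) -> list[UtilizationRow]:
    """Any-use proportions and count intensities per category, by stratum.

    ``strata`` maps every cohort patient id to one of exactly two labels
    (order of first appearance is preserved); rows whose stratum user count
    falls in 1..threshold-1 are marked suppressed and rendered as "NR".
    """
    labels: list[str] = []
    members_by_label: dict[str, list] = {}
    for member in cohort:
        label = strata.get(member.patient_id)
        if label is None:
            raise ValueError(f"patient {member.patient_id} missing a stratum label")
        if label not in members_by_label:
            labels.append(label)
            members_by_label[label] = []
        members_by_label[label].append(member)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 strata, got {labels}")

    rows = []
    for category in categories:
        users, counts_by_label = [], []
        for label in labels:
            counts = []
            for member in members_by_label[label]:
                in_period = _claims_in_period(
                    claims_by_patient.get(member.patient_id, []),
                    member.dx_month,
                    member.censor_month,
                    period,
                )
                counts.append(
                    sum(1 for c in in_period if c.service_category == category)
                )
            counts_by_label.append(counts)
            users.append(sum(1 for k in counts if k > 0))
        stratum_n = tuple(len(members_by_label[label]) for label in labels)
        table = [[u, n - u] for u, n in zip(users, stratum_n)]
        try:
            _, _, p_any = chi_square(table)
        except ValueError:
            p_any = None
        mx, sdx, my, sdy, p_mean = mean_compare(*counts_by_label)
        rows.append(
            UtilizationRow(
                category=category,
                period=period,
                stratum_n=stratum_n,
                users=tuple(users),
                pct=tuple(
                    round_half_up(100 * u / n, 1) for u, n in zip(users, stratum_n)
                ),
                mean=(mx, my),
                sd=(sdx, sdy),
                p_any_use=p_any,
                p_mean=p_mean,
                suppressed=any(0 < u < suppression_threshold for u in users),
            )
        )
    return rows


def render_utilization(
    rows: Sequence[UtilizationRow],
    labels: Sequence[str],
    suppression_threshold: int = SUPPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Publication-style table; suppressed small cells appear as "NR"."""
    out = []
    for row in rows:
        rendered: dict[str, object] = {"category": row.category, "period": row.period}
        for label, n_users, pct in zip(labels, row.users, row.pct):
            if row.suppressed and 0 < n_users < suppression_threshold:
                rendered[f"{label}_n"] = "NR"
                rendered[f"{label}_pct"] = "NR"
            else:
                rendered[f"{label}_n"] = n_users
                rendered[f"{label}_pct"] = pct
        rendered["p_any_use"] = _fmt_p(row.p_any_use)
        for label, mean, sd in zip(labels, row.mean, row.sd):
            rendered[f"{label}_mean"] = round_half_up(mean, 2)
            rendered[f"{label}_sd"] = round_half_up(sd, 2) if sd is not None else ""
        rendered["p_mean"] = _fmt_p(row.p_mean)
        out.append(rendered)
    return pd.DataFrame(out)


def _fmt_p(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.01:
        return "<0.01"
    return f"{round_half_up(p, 2):.2f}"
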