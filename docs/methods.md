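# Methods

## Setting and measures

The pipeline evaluates how well claims-based case definitions of incident
bone metastasis (BM) agree with a cancer registry's M1b sub-stage in men
diagnosed with metastatic (AJCC M1) prostate cancer. The registry measure is
a single boolean per patient (M1b at diagnosis); the claims measures are
deterministic rules over coded billing claims from three settings
(inpatient, outpatient, carrier/physician). Agreement is summarised by
sensitivity, specificity and positive predictive value of each claims flag
against the registry flag, with 95% binomial confidence intervals.

Throughout, the registry diagnosis anchor has **month** precision (the
registry does not release exact diagnosis dates), while claims carry full
service dates. All window logic that mixes the two therefore operates on
calendar months: the concurrency window is the three months
{m−1, m, m+1} around the diagnosis month m, the standard allowance for
claims lagging or leading the event month. Day-level arithmetic is used only
for gap rules between two claims (the "within 90 days" conditions), where
both dates are known.

## Cohort selection

Inclusion: male, age ≥ 66 at diagnosis, incident prostate cancer diagnosed
2005–2007, AJCC M1 (M1a/M1b/M1c), and Medicare Parts A and B both active
with no HMO enrollment for the 13 calendar months from 12 months before
diagnosis through the diagnosis month ("12 months prior to and including the
month of diagnosis" read literally as 13 distinct months). Exclusion: any
other cancer within 5 years before diagnosis (carried as a pre-computed
boolean; sequence-number logic is out of scope). The first accrual year in
which the M1b sub-stage became available (2004) is excluded by the year
filter.

Each excluded patient is attributed exactly one reason — the first failing
rule in the fixed order demographic → year → stage → enrollment → HMO →
prior cancer. The source study does not state an attribution order; a fixed
order makes the exclusion log a partition and the cascade reproducible.
Retained patients are censored at the earliest of post-diagnosis HMO entry,
loss of Part A and/or B (a missing enrollment month counts as loss), or the
study end, December 2009. Death-based censoring is not modelled.

## Classification rules

* **Approach 1**: ≥ 1 claim in the window, any setting, BM code (default
  ICD-9 198.5) in any diagnosis position.
* **Approach 2**: inpatient claim with the BM code in position 1 or 2; OR an
  outpatient BM-coded claim "paired" with a BM diagnostic/treatment
  procedure; OR a carrier evaluation-and-management claim with the BM code.
  The pairing granularity is genuinely open in the source description; the
  implementation accepts either a single claim carrying both the BM code and
  a pairing-category service, or a same-date outpatient procedure claim of a
  pairing category — the wider, auditable reading. Both the pairing
  categories (bone scan, bone biopsy, IV bisphosphonate) and the
  interpretation are configurable via the `CodeSet`.
* **Approach 3**: inpatient BM-coded claim in any position; OR ≥ 2
  outpatient BM-coded claims on distinct service dates at most 90 days
  apart. A gap of exactly 90 days counts as inside ("90-day window" read
  inclusively). Duplicate billing lines on one date count once.
* **Expanded Approach 3**: Approach 3, OR ≥ 2 outpatient claims of the
  expanded test categories (PSA test, bone/joint imaging) on distinct dates
  ≤ 90 days apart inside the window. The two tests may be of either category
  in any combination (literal disjunction; a same-category-only variant is a
  configuration away).
* **BM ever**: the same rule evaluated over all claims from the month before
  diagnosis onward, with no upper bound.
* **Two-step diagnostic filter**: a diagnostic-category claim (bone scan,
  bone/joint imaging, bone biopsy) is kept only if some BM-coded claim
  follows within 90 days (same day counts); services intended to rule BM
  out should not carry the BM code, so unconfirmed diagnostic claims are
  treated as uninformative.

Claims are keyed on a `service_category` tag rather than raw CPT/HCPCS
procedure codes: no public code list pins down categories such as "bone
scan", so the mapping is left to the data preparer and the category sets are
configurable (`CodeSet`, YAML-loadable). ICD-9 codes are matched as exact
decimal-pointed strings ("198.5"), avoiding undotted-code ambiguity.

## Statistics

Sensitivity tp/(tp+fn), specificity tn/(fp+tn), PPV tp/(tp+fp); a zero
denominator yields an explicit "undefined", never 0. Confidence intervals:
Wald (normal approximation) by default, Wilson score as an option, both at
z = Φ⁻¹(0.975) ≈ 1.959964 and truncated to [0, 1]. Both methods reproduce
the published Approach-3 bounds at 3 decimals but disagree with each other
in the last digit elsewhere (e.g. the Approach-1 sensitivity lower bound:
Wald 0.575, Wilson 0.574), and no single standard method reproduces every
published bound — the original software's method is unrecoverable, so only
method-robust bounds are treated as checkable.

Subgroup utilization comparisons: Pearson chi-square without continuity
correction (cells are large throughout; the identity χ² = z² against the
pooled two-proportion z-test is property-tested), and Welch's t-test for
count intensities (the source names no test for means; Welch avoids the
equal-variance assumption). Rendered tables suppress any stratum count in
1..10 as "NR" per the common small-cell reporting convention (threshold
configurable); zero is reportable.

Display rounding is half-up: 3 decimals for proportions, 1 for percentages,
matching the precision of the published tables.

## Synthetic cohort: what it emulates and how it is calibrated

The real linked data are access-restricted, so the generator emits a
structurally faithful stand-in: one registry row per patient, claim lines
with setting / service date / ordered diagnosis codes / service category /
E&M flag, and monthly Part A/B/HMO enrollment spans. Defaults are the study
conditions: 2,708 eligible men (1,694 registry-BM-positive), accrual
2005–2007, study end 2009-12, plus 50 decoys per exclusion reason, each
violating exactly one rule (age 64; one baseline HMO month at m−3; one
baseline Part-B gap at m−5; prior cancer; M0 stage) so every rule is
individually exercised.

**Calibration.** The published validation table reports each rule's three
statistics to 3 decimals plus marginal counts. `derive_crosstab` inverts the
rounding by exhaustive integer search: the unique (tp, fp, fn, tn) with
tp + fp equal to the flagged margin whose three ratios all round half-up to
the printed values. For the study inputs the solutions are unique:
a1 (1013, 468, 681, 546), a2 (941, 422, 753, 592), a3 (813, 385, 881, 629);
the a3 tp/fn cells independently match the published within-M1b stratum
sizes (813/881). For the expanded rule only sensitivity 0.581 and
specificity 0.558 are printed; the specificity numerator (566/1014) is
unique by rounding, while the sensitivity numerator is ambiguous (984 or
985) and is resolved by requiring the Wald CI to reproduce the printed
bounds (985 → 0.558–0.605 exactly), giving +172 true positives and +63
false positives over the base rule. The printed expanded-specificity lower
bound (0.527) is one final-digit off any standard method's value (0.528);
CI bounds are therefore used only to break rounding ties, by minimum
deviation, never as exact constraints.

**Joint structure.** Only marginal counts per rule are published
(1481 ≥ 1363 ≥ 1198). The generator adopts the nested structure
A3⁺ ⊆ A2⁺ ⊆ A1⁺ within each registry arm — the unique maximal-overlap
joint distribution consistent with those margins (logic alone forces only
A2⁺ ⊆ A1⁺ and A3⁺ ⊆ A1⁺). This is a convention, not an inference; any
joint structure matching the margins is admissible, and the cross-tab
invariants hold for arbitrary consistent cell prescriptions.

**Recipes.** Each eligible patient gets one claim recipe realising its
designated statuses simultaneously: inpatient BM claim, code position
configurable (position ≤ 2 → positive under all three rules; a position ≥ 3
variant blocks the Approach-2 inpatient arm); single carrier E&M BM claim
(rules 1+2); single unpaired outpatient BM claim (rule 1 only); or no
in-window BM claim. Expanded-positive patients additionally receive a PSA
and a bone-imaging claim 20 days apart inside the window. Utilization noise
is drawn Bernoulli per service category with stratum probabilities defaulting
to the published column percentages — registry-positive strata split by
Approach-3 status; registry-negative patients use the published
no-registry-BM column, since the joint breakdown is unpublished — and is
placed so it cannot flip an engineered status: post-window claims carry no
BM code, and all in-window utilization claims for a patient share a single
service date distinct from the recipe dates (the expanded rule requires two
distinct dates; Approach-2 pairing requires same-date co-occurrence with a
BM-coded claim). A fraction (default 0.1) of registry-positive,
concurrent-negative patients receive a BM claim six months after diagnosis,
exercising the "ever" measure.

**What the fixture does not emulate.** Post-diagnosis any-use proportions
are drawn independently for the window and follow-up periods, so their union
overshoots the published follow-up columns for high-frequency categories;
count intensities beyond PSA tests are token (one claim per user); billing
amounts, providers, survival and joint dependence between categories are out
of scope. Passing tests therefore demonstrate the correctness of the rules,
the cascade and the statistics on structurally realistic data — not
distributional realism of utilization, and not the measurement properties of
the registry M1b variable itself.

A probabilistic mode draws claim-flag statuses i.i.d. at a chosen true
sensitivity/specificity instead of engineering exact cells; a parameter-
recovery suite checks that the pipeline's own 95% CIs cover the truth at
approximately the nominal rate (200 replicates of 300 positives / 200
negatives — sizes chosen to keep the default suite fast while leaving
binomial noise well below the checked coverage margin).

## Numerical and degenerate-input choices

Half-up rounding is done in decimal arithmetic (no float re-rounding);
the consistency search compares printed decimals exactly at their printed
precision. Zero-denominator statistics are flagged undefined. Chi-square
refuses tables with a zero expected cell and advises collapsing. Intervals
are clamped to contain the point estimate (the Wilson upper bound at k = n
can fall 1 ulp below 1). Patients with no enrollment rows are excluded as
lacking continuous coverage, with a warning. Fixture generation validates
the full specification (margins, nesting, probability ranges) before
writing any file, and is byte-deterministic for a fixed seed.

## Known limitations

The exclusion-reason attribution order, the pairing interpretation, the
inclusive 90-day boundary and the nested joint structure are documented
conventions where the source is silent; all are configurable or isolated.
The generator guarantees published-table reproduction by construction, so
end-to-end agreement is a check of internal consistency of pipeline +
calibration, not external validation of the rules on real claims. ICD-10
logic, other metastatic sites, comorbidity-index computation and survival
or cost analysis are out of scope.
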