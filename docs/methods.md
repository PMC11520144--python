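# Methods

## Unit of analysis and data model

The unit of analysis is the hospitalization encounter: a patient admitted
three times contributes three independent admissions. Each admission carries
demographics, a raw financial class, the billed ICD-10 code list and the
billed DRG code; clinical evidence lives in five source tables (labs,
cultures, flowsheet observations, medication events, procedures). Sources
whose rules reach before the index admission — echo ejection fraction, BNP,
the heart-failure problem list, HIV screens, transplant surgeries — link at
the patient level; everything else links by encounter. Files are
comma-delimited UTF-8 with ISO-8601 timestamps; a schema config remaps
foreign column names so other extracts can be adapted without code changes.

De-identification replaces every patient and encounter id with a truncated
SHA-256 of `salt:id` and every timestamp with the fractional-day offset from
that patient's earliest recorded event. Keying the digest with the id gives
per-patient distinct hashes from one cohort-level salt while keeping the
mapping reproducible for testing; offsets preserve orderings and all
inter-event intervals exactly. Offsets are fractional, not whole days,
because the post-operative anemia rule needs hour resolution.

## Phenotype rules

Nineteen disease rules are shipped, each tied to the DRG severity tier it
justifies (12 CC, 7 MCC) and to a list of qualifying ICD patterns.
Inequality strictness follows the reference definitions literally:
pH < 7.35 strict, sodium ≤ 134 and eGFR ≤ 30 and GCS ≤ 8 inclusive,
BMI > 40 / < 19 strict on both sides, blood loss ≥ 300 mL and urine colony
count ≥ 100,000 CFU/mL inclusive. Every boundary is unit-tested on both
sides. All thresholds sit in `RuleParams` (YAML-serializable) so a site can
retune them; the defaults are the reference definitions.

Interpretation choices where the definitions were open:

- "Within the 12 months prior to admission" is a fixed 365-day window ending
  at admit time, inclusive at both ends, and the index admission's own
  results also count (window effectively `[admit − 365 d, discharge]`).
- "Positive troponin" uses the lab's abnormal flag, because a numeric cut is
  assay-dependent; the flag string is configurable.
- The post-op anemia anchor is the timestamp of the blood-loss observation;
  the hemoglobin window is the half-open `(anchor, anchor + 24 h]` — a draw
  at the anchor itself is treated as pre-operative.
- The respiratory-failure surgery exclusion counts only `surgery_case`
  procedures: a coronary stent is a cath-lab procedure, not an OR case.
- End-stage renal disease and severe malnutrition are presence-defined
  (any dialysis-flow documentation; any TPN event).
- The sodium rule reads the serum sodium analyte; the heart-failure problem
  list is modeled as a boolean flowsheet observation.
- The inpatient-death rule has no qualifying ICD list and is therefore
  exempt from omission flagging, but it still drives DRG upgrades (MCC).

Evaluation is deterministic and order-invariant: evidence is de-duplicated
and sorted by content, so permuting input records never changes a call.
All rules except the respiratory-failure exclusion are existential —
adding a record can only flip a flag false→true.

## DRG parsing and upgrade evaluation

Catalogue descriptions are classified by their trailing phrase:
`… WITH MCC` → MCC, `… WITH CC` → CC, `… WITHOUT CC/MCC` (or
`… WITHOUT MCC` / `… WITHOUT CC`) → Base. A description with no recognized
phrase is a Singlet candidate; a family-level pass promotes it to Base when
leveled siblings share its stripped family, otherwise it stays a true
Singlet whose severity cannot be modified. The doublet arm `… WITH CC/MCC`
satisfies CC when it is the billed DRG but serves as the MCC target when an
upgrade is proposed — the most conservative reading that still allows the
partial modification doublets admit.

Per admission the required tier is the maximum over all detected diseases
(highest tier wins; at most one flag per admission). If the billed DRG is a
Singlet, or the billed tier already meets the requirement, no flag is
raised. The proposed DRG is the billed family's entry at the required tier;
if the family lacks it, the highest tier above the billed one is proposed
instead (the upgrade type then encodes the tier actually proposed), and
cross-family regrouping is never attempted. A DRG never proposes itself and
the delta RWF is floored at zero. Admissions whose billed DRG is absent
from the catalogue are skipped and logged, mirroring the exclusion of
admissions without an assigned DRG. Known limitation: DRG-specific
exclusions (e.g. obesity implied by a bariatric-surgery DRG) are not
modeled; only upward ("rule-in") auditing is supported.

## Payors and revenue

Financial classes consolidate to three payor classes — Medicare (incl.
Medicare Advantage), Medi-Cal (incl. Medicaid), and Private as the default
bucket for everything unmapped. Each class carries an estimated
dollars-per-RWF rate (defaults $20,000 / $10,000 / $7,500); both the map
and the rates are config files. All currency arithmetic is exact `Decimal`
cents: a summary cell's revenue is its summed RWF points times the rate,
rounded half-up at the cell level; the grand total is the exact sum of
cells; per-type subtotals are additionally rounded to the dollar for
display. Dollar outputs are labeled estimates — real reimbursement is
contract-specific.

## Statistics

- Incidence intervals are exact Clopper–Pearson (`statsmodels`
  `proportion_confint(method="beta")`); Wilson is available behind the
  `method` flag.
- Binary SMD: `|p1 − p2| / sqrt((p1(1−p1) + p2(1−p2))/2)`, 0 for degenerate
  groups. Multi-category SMD is the Mahalanobis-type generalization over the
  first K−1 category proportions with pooled multinomial covariance (the
  standard definition in the covariate-balance literature); it reduces to
  the binary form for two categories. Banding convention: small 0–0.4,
  medium 0.4–0.6, large 0.6–1.0.
- Reference-group comparisons are Pearson chi-square on the 2×2 subtable
  without continuity correction (large-sample setting); Fisher's exact test
  is switchable for small tables. Reference categories: Caucasian
  non-Hispanic, private payors, ages 36–64. A zero margin returns p = 1
  with a warning. No multiple-testing correction is applied; p-values are
  reported raw.
- The audit summary table reports, per disease, the detected count, the
  missing-ICD count and percentage (of detected), the inadequate-DRG count
  and percentage (of detected; an admission counts for a disease when that
  disease is among its upgrade flag's driving diseases), and the
  not-sensitive count — admissions carrying a qualifying code without
  meeting the clinical criteria — as a percentage of all code-bearing
  admissions. Published analogues of this table use inconsistent
  denominators; this package recomputes every percentage from its own
  counts, so row percentages always reproduce from the row.

## Synthetic cohort generator

The generator emulates the structure of a one-year academic-hospital
cohort: defaults are per-disease prevalences of 0.1%–28.7% and omission
rates of 0–80.3% matching a published 34,104-admission audit year, the
payor mix (14% Medi-Cal / 38.3% Medicare / 47.7% private), sex, race and
age-band mixes of the same cohort, and a 10.8% Singlet DRG share. Disease
states are drawn independently per admission; two closure rules keep the
answer key consistent with the injected evidence (acute MI implies
myocardial injury; a blood-loss-anemia admission carries an OR case and
therefore cannot satisfy respiratory failure's no-surgery requirement).

Positive evidence is sampled just past each threshold (e.g. pH
U(7.20, 7.349)) and safe-side noise strictly on the negative side (pH
U(7.36, 7.45)), which stress-tests boundary handling; each false disease
receives a safe-side record with probability 0.2. Billed DRGs follow an
under-coding scheme: one tier below the justified level with probability
u = 0.10, two tiers with u²/2, renormalized to the feasible steps — chosen
once as a plausible mis-coding rate that exposes all three upgrade types
and yields an upgrade-eligible share near the published 5.8%. Qualifying
codes are emitted with probability 1 − omission rate; false diseases
receive their code at a 2% rate to exercise the not-sensitive column.

What the generator does **not** emulate: correlated comorbidity (diseases
are independent, so the share of admissions missing any code runs a few
points above the published 32.9%), longitudinal patient trajectories
(one patient per admission), treatment/documentation context, and free-text
notes. Passing the end-to-end oracle therefore demonstrates that the
pipeline recovers exactly the structure the rules define — not clinical
realism beyond that structure.

## Problem sizes and numerical choices

The end-to-end oracle runs at 500 admissions, statistical recovery at
5,000 (each configured omission rate must land inside its exact-binomial
99% interval), interval coverage over 200 replicates of 300-admission
single-disease cohorts (Clopper–Pearson is conservative, so coverage is
checked against [0.93, 1.0]), and brute-force equivalence over 100 random
mini-cohorts (≤ 20 admissions) and 30 random mini-catalogues, all with
fixed seeds. ICD normalization is uppercase/trim with the dot retained;
wildcard patterns match their bare root by default (`children_only`
switches to strict child matching). Ties in target-DRG selection (same
family and tier) break by lowest DRG code; they cannot occur in
well-formed catalogues.
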