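# drgaudit

Rules-based auditing of inpatient ICD/DRG coding from raw structured EHR
data.

Hospital claims are coded by hand: after discharge, a medical coder reviews
the chart and assigns ICD-10 diagnosis codes, which in turn drive the
admission's Diagnosis-Related Group (DRG) and its severity modifier — Base,
CC (comorbid condition) or MCC (major comorbid condition). High-acuity
diagnoses that never make it into the claim depress the DRG severity tier
and the hospital's case-mix-weighted reimbursement. `drgaudit` is for
clinical informaticists and revenue-integrity teams who want to audit that
gap automatically, without manual chart review:

1. **Phenotyping** — 19 computable disease rules (12 CC-tier, 7 MCC-tier)
   are evaluated per admission against labs, cultures, flowsheets,
   medication events and procedure logs: e.g. acidemia (arterial pH < 7.35),
   hyponatremia (Na ≤ 134 mmol/L), CKD (MDRD eGFR ≤ 30), altered mental
   status (GCS ≤ 8), bacteremia (≥ 2 positive blood cultures), severe
   malnutrition (TPN documented).
2. **ICD omission flagging** — an admission whose clinical data satisfy a
   rule but whose billed codes match none of that disease's qualifying ICD
   patterns (literals like `E87.1` or families like `I50.*`) is flagged as
   missing applicable ICD data.
3. **DRG upgrade evaluation** — DRG descriptions are parsed into severity
   tiers (`… WITH MCC`, `… WITH CC`, `… WITHOUT CC/MCC`, Singlet) and
   modifier-stripped families; if the highest tier justified by the detected
   diseases exceeds the billed tier, the admission gets a single upgrade
   flag (base→CC, base→MCC or CC→MCC) pointing at the same-family DRG.
4. **Revenue valuation** — the delta in relative weighting factor (RWF)
   between the proposed and billed DRG is valued per consolidated payor
   class (estimated $20,000/RWF private, $10,000 Medicare, $7,500 Medi-Cal),
   in exact decimal cents.
5. **Statistics** — incidence rates with exact Clopper–Pearson intervals,
   standardized mean differences and chi-square reference-group tests
   comparing the accurately-coded and unbilled groups, and the 25-code
   payor-limit census.

A seeded synthetic-cohort generator (`drgaudit.synth`) emits CSV cohorts
with known latent disease states, omission rates and under-coded DRGs, so
the whole pipeline is testable end to end with no data download.

## Worked example

```bash
drg-audit fixtures --out demo --seed 1 --n 500
drg-audit run --cohort demo --drg-table demo/drg_catalogue.csv --out reports
```

`reports/upgrade_counts.json` from that exact run:

```json
{
  "base_to_CC": 13,
  "base_to_MCC": 0,
  "CC_to_MCC": 12,
  "total_upgrade_eligible": 25,
  "estimated_lost_revenue_usd": "127327.00", ...
}
```

Of the 500 synthetic admissions, 25 (5.0%) were billed below the severity
tier their clinical data justified — 13 deserved a CC modifier over a base
DRG and 12 an MCC over a CC — and closing those gaps would recover an
estimated $127,327 at the default payor rates. `reports/audit_table.csv`
breaks detection, omission and upgrade counts down per disease,
`reports/revenue_table.csv` splits dollars by upgrade type × payor, and
`reports/balance_table.csv` reports the SMD and reference-group p-values
for sex, race/ethnicity, payor and age group. Dollar figures are estimates:
RWF rates are configurable averages, not contract terms.

The same pipeline is available as a library:

```python
from drgaudit import (SynthConfig, generate_cohort, build_catalogue,
                      demo_catalogue_frame, run_pipeline)
cohort, truth = generate_cohort(SynthConfig(n_admissions=500, seed=1))
result = run_pipeline(cohort, build_catalogue(demo_catalogue_frame()))
print(result.upgrade_counts)   # {'base_to_CC': 13, 'base_to_MCC': 0, ...}
```

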