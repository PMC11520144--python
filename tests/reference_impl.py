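"""Naive reference implementations used as independent oracles in tests.

These deliberately avoid the package's indexed evaluation path: every rule is
re-derived by scanning the full record lists per admission, and upgrade-target
selection is an exhaustive search over the catalogue. Slow and simple on
purpose.
"""
from __future__ import annotations

from drgaudit.model import Cohort, to_days


def _linked_enc(records, enc):
    return [r for r in records if getattr(r, "encounter_id", None) == enc]


def _linked_pat(cohort, records, pid):
    enc_of = {a.encounter_id: a.patient_id for a in cohort.admissions}
    out = []
    for r in records:
        rp = getattr(r, "patient_id", None)
        re = getattr(r, "encounter_id", None)
        if rp == pid or (rp is None and enc_of.get(re) == pid):
            out.append(r)
    return out


def _mdrd(scr, age, sex, black):
    v = 175.0 * scr ** -1.154 * age ** -0.203
    if sex == "female":
        v *= 0.742
    if black:
        v *= 1.212
    return v


def naive_detect(cohort: Cohort, adm) -> dict[str, bool]:
    """Re-derive all 19 disease flags for one admission by brute scanning."""
    enc, pid = adm.encounter_id, adm.patient_id
    admit, disch = to_days(adm.admit_time), to_days(adm.discharge_time)
    labs = _linked_enc(cohort.labs, enc)
    flows = _linked_enc(cohort.flowsheets, enc)
    meds = _linked_enc(cohort.medications, enc)
    procs = _linked_enc(cohort.procedures, enc)
    cults = _linked_enc(cohort.cultures, enc)

    out = {}
    out["Acidemia"] = any(l.analyte == "arterial_pH" and l.numeric_value is not None
                          and l.numeric_value < 7.35 for l in labs)
    out["Bacteremia"] = sum(1 for c in cults
                            if c.specimen == "blood" and c.positive) >= 2

    anemia = False
    for fl in flows:
        if fl.measure == "intraop_blood_loss_mL" and isinstance(fl.value, float) \
                and fl.value >= 300:
            t0 = to_days(fl.observed_time)
            for l in labs:
                if l.analyte == "hemoglobin" and l.numeric_value is not None \
                        and l.numeric_value < 12 \
                        and t0 < to_days(l.collected_time) <= t0 + 1.0:
                    anemia = True
    out["Blood Loss Anemia"] = anemia

    chf = False
    for fl in _linked_pat(cohort, cohort.flowsheets, pid):
        t = to_days(fl.observed_time)
        if not admit - 365 <= t <= disch:
            continue
        if fl.measure == "ejection_fraction" and isinstance(fl.value, float) \
                and fl.value <= 30:
            chf = True
        if fl.measure == "problem_list_heart_failure" \
                and str(fl.value).lower() in ("true", "1", "1.0", "yes", "active"):
            chf = True
    for l in _linked_pat(cohort, cohort.labs, pid):
        if l.analyte == "BNP" and l.numeric_value is not None \
                and l.numeric_value > 900 \
                and admit - 365 <= to_days(l.collected_time) <= disch:
            chf = True
    out["Chronic CHF"] = chf

    out["Chronic Kidney Disease"] = any(
        l.analyte == "serum_creatinine" and l.numeric_value is not None
        and l.numeric_value > 0 and adm.age_years > 0
        and _mdrd(l.numeric_value, adm.age_years, adm.sex,
                  adm.race_ethnicity == "Black") <= 30
        for l in labs)
    out["Delirium"] = any(
        fl.measure == "CAM_result"
        and str(fl.value).lower() in ("positive", "true", "1", "1.0")
        for fl in flows)
    out["Extremes of BMI"] = any(
        fl.measure == "BMI" and isinstance(fl.value, float)
        and (fl.value > 40 or fl.value < 19) for fl in flows)
    out["HIV"] = any(
        l.analyte == "HIV_screen" and l.abnormal_flag == "positive"
        and to_days(l.collected_time) <= disch
        for l in _linked_pat(cohort, cohort.labs, pid)) or any(
        m.drug == "zidovudine" and m.event_kind == "order_active" for m in meds)
    out["Hyponatremia"] = any(
        l.analyte == "sodium" and l.numeric_value is not None
        and l.numeric_value <= 134 for l in labs)
    troponin_pos = any(l.analyte == "troponin" and l.abnormal_flag == "positive"
                       for l in labs)
    out["Myocardial Injury"] = troponin_pos
    out["Transplant"] = any(
        p.kind == "transplant_surgery" and to_days(p.event_time) <= disch
        for p in _linked_pat(cohort, cohort.procedures, pid)) or any(
        m.drug == "tacrolimus" and m.event_kind == "administration" for m in meds)
    out["UTI"] = any(c.specimen == "urine" and c.colony_count is not None
                     and c.colony_count >= 100_000 for c in cults)
    out["Acute MI"] = troponin_pos and any(p.kind == "coronary_stent" for p in procs)
    out["Acute Pancreatitis"] = any(
        l.analyte == "amylase" and l.numeric_value is not None
        and l.numeric_value > 1000 for l in labs) or any(
        l.analyte == "lipase" and l.numeric_value is not None
        and l.numeric_value > 450 for l in labs)
    out["Altered Mental Status"] = any(
        fl.measure == "GCS_total" and isinstance(fl.value, float)
        and fl.value <= 8 for fl in flows)
    out["End Stage Renal Disease"] = any(fl.measure == "dialysis_flow"
                                         for fl in flows)
    out["Inpatient Death"] = adm.died_inpatient
    out["Respiratory Failure"] = any(
        fl.measure == "airway_device"
        and str(fl.value) in ("endotracheal_tube", "high_flow_nasal_cannula")
        for fl in flows) and not any(p.kind == "surgery_case" for p in procs)
    out["Severe Malnutrition"] = any(m.drug == "TPN" for m in meds)
    return out


def naive_evaluate(cohort: Cohort) -> dict[tuple[str, str], bool]:
    return {(adm.encounter_id, d): v
            for adm in cohort.admissions
            for d, v in naive_detect(cohort, adm).items()}


def naive_upgrade_target(billed, required_rank: int, entries):
    """Exhaustive search over all catalogue entries for the proposed DRG.

    Returns (target entry or None). Search restricted to the billed family;
    prefer the exact required tier, else the highest tier above billed.
    """
    if billed.billed_rank is None or required_rank <= billed.billed_rank:
        return None
    same_family = [e for e in entries
                   if e.family == billed.family and e.target_rank is not None
                   and e.target_rank > billed.billed_rank
                   and e.drg_code != billed.drg_code]
    exact = sorted([e for e in same_family if e.target_rank == required_rank],
                   key=lambda e: e.drg_code)
    if exact:
        return exact[0]
    if not same_family:
        return None
    best = max(e.target_rank for e in same_family)
    return sorted([e for e in same_family if e.target_rank == best],
                  key=lambda e: e.drg_code)[0]
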