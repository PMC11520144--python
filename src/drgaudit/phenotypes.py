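"""Rules-based disease phenotyping.

Nineteen computable phenotypes, each tied to a DRG severity tier (CC or MCC),
are evaluated per admission against structured EHR sources: labs, cultures,
flowsheet observations, medication events, and procedure logs. Sources that
carry history (echo ejection fraction, BNP, heart-failure problem list, HIV
screens, transplant surgeries) are evaluated at the patient level with a
look-back window; everything else is confined to the index encounter.

All thresholds live in :class:`RuleParams` so a site can retune them from a
config file; the shipped defaults are the audit's reference definitions.
Inequality strictness follows those definitions literally (pH < 7.35 strict,
sodium <= 134 inclusive, GCS <= 8 inclusive, BMI > 40 / < 19 strict, blood
loss >= 300 mL inclusive).
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import yaml

from .model import AdmissionRecord, Cohort, TimeLike, to_days

logger = logging.getLogger(__name__)

CC = "CC"
MCC = "MCC"


@dataclass(frozen=True)
class RuleParams:
    """Tunable clinical thresholds for the phenotype rulebook."""

    ph_max: float = 7.35                # arterial pH below this => acidemia (strict)
    min_positive_blood_cultures: int = 2
    ebl_min_ml: float = 300.0           # intraoperative blood loss, inclusive
    postop_hgb_max: float = 12.0        # g/dL, strict
    postop_window_days: float = 1.0     # first 24 h after surgery
    ef_max: float = 30.0                # %, inclusive
    bnp_min: float = 900.0              # pg/mL, strict
    lookback_days: float = 365.0        # "12 months prior to admission"
    egfr_max: float = 30.0              # mL/min/1.73m2, inclusive
    bmi_high: float = 40.0              # strict
    bmi_low: float = 19.0               # strict
    sodium_max: float = 134.0           # mmol/L, inclusive
    amylase_min: float = 1000.0         # U/L, strict
    lipase_min: float = 450.0           # U/L, strict
    gcs_max: float = 8.0                # inclusive
    urine_colony_min: float = 100_000.0  # CFU/mL, inclusive
    troponin_positive_flag: str = "positive"
    airway_devices: tuple[str, ...] = ("endotracheal_tube", "high_flow_nasal_cannula")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["airway_devices"] = list(d["airway_devices"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RuleParams":
        d = dict(d)
        if "airway_devices" in d:
            d["airway_devices"] = tuple(d["airway_devices"])
        return cls(**d)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RuleParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class Evidence:
    table: str
    locator: str
    detail: str


@dataclass
class PhenotypeCall:
    encounter_id: str
    disease_name: str
    detected: bool
    evidence: list[Evidence] = field(default_factory=list)


@dataclass(frozen=True)
class PhenotypeRule:
    disease_name: str
    modifier_level: str  # CC | MCC
    qualifying_icd_patterns: tuple[str, ...]
    predicate: Callable[[AdmissionRecord, Cohort, RuleParams], list[Evidence]]


def egfr_mdrd(serum_creatinine_mg_dl: float, age_years: float, sex: str,
              black_race: bool) -> float:
    """4-variable MDRD estimated GFR (mL/min/1.73 m^2).

    175 * Scr^-1.154 * age^-0.203 * 0.742 (if female) * 1.212 (if Black).
    """
    if serum_creatinine_mg_dl <= 0 or age_years <= 0:
        raise ValueError("creatinine and age must be positive")
    value = 175.0 * serum_creatinine_mg_dl ** -1.154 * age_years ** -0.203
    if sex == "female":
        value *= 0.742
    if black_race:
        value *= 1.212
    return value


def within_window(events: Sequence, time_of: Callable[[object], TimeLike],
                  anchor_time: TimeLike, lookback_days: float,
                  direction: str = "before") -> list:
    """Events within ``lookback_days`` of the anchor; both boundaries inclusive."""
    if lookback_days <= 0:
        raise ValueError("lookback_days must be positive")
    anchor = to_days(anchor_time)
    if direction == "before":
        lo, hi = anchor - lookback_days, anchor
    elif direction == "after":
        lo, hi = anchor, anchor + lookback_days
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return [e for e in events if lo <= to_days(time_of(e)) <= hi]


# ---------------------------------------------------------------------------
# Predicates (each returns the list of satisfying records as Evidence)
# ---------------------------------------------------------------------------

def _ev(table: str, rec, detail: str) -> Evidence:
    return Evidence(table, repr(rec), detail)


def _enc_labs(adm, cohort, analyte):
    return [r for r in cohort.encounter_records("labs", adm.encounter_id)
            if r.analyte == analyte]


def _acidemia(adm, cohort, p):
    return [_ev("labs", r, f"arterial pH {r.numeric_value}")
            for r in _enc_labs(adm, cohort, "arterial_pH")
            if r.numeric_value is not None and r.numeric_value < p.ph_max]


def _bacteremia(adm, cohort, p):
    pos = [r for r in cohort.encounter_records("cultures", adm.encounter_id)
           if r.specimen == "blood" and r.positive]
    if len(pos) >= p.min_positive_blood_cultures:
        return [_ev("cultures", r, "positive blood culture") for r in pos]
    return []


def _blood_loss_anemia(adm, cohort, p):
    ebls = [r for r in cohort.encounter_records("flowsheets", adm.encounter_id)
            if r.measure == "intraop_blood_loss_mL"
            and isinstance(r.value, float) and r.value >= p.ebl_min_ml]
    out = []
    for ebl in ebls:
        anchor = to_days(ebl.observed_time)
        for hgb in _enc_labs(adm, cohort, "hemoglobin"):
            if hgb.numeric_value is None:
                continue
            t = to_days(hgb.collected_time)
            # window is (surgery end, +24 h]: a draw at the anchor itself is pre-op
            if anchor < t <= anchor + p.postop_window_days \
                    and hgb.numeric_value < p.postop_hgb_max:
                out.append(_ev("flowsheets", ebl, f"EBL {ebl.value} mL"))
                out.append(_ev("labs", hgb, f"post-op Hgb {hgb.numeric_value}"))
    return out


def _chf_window(adm, events, time_of, p):
    """Look-back covering [admit - lookback, discharge]: historic results within
    12 months plus the index admission's own results both count."""
    lo = to_days(adm.admit_time) - p.lookback_days
    hi = to_days(adm.discharge_time)
    return [e for e in events if lo <= to_days(time_of(e)) <= hi]


def _chronic_chf(adm, cohort, p):
    out = []
    efs = [r for r in cohort.patient_records("flowsheets", adm.patient_id)
           if r.measure == "ejection_fraction" and isinstance(r.value, float)]
    for r in _chf_window(adm, efs, lambda e: e.observed_time, p):
        if r.value <= p.ef_max:
            out.append(_ev("flowsheets", r, f"EF {r.value}%"))
    bnps = [r for r in cohort.patient_records("labs", adm.patient_id)
            if r.analyte == "BNP" and r.numeric_value is not None]
    for r in _chf_window(adm, bnps, lambda e: e.collected_time, p):
        if r.numeric_value > p.bnp_min:
            out.append(_ev("labs", r, f"BNP {r.numeric_value} pg/mL"))
    probs = [r for r in cohort.patient_records("flowsheets", adm.patient_id)
             if r.measure == "problem_list_heart_failure"]
    for r in _chf_window(adm, probs, lambda e: e.observed_time, p):
        if str(r.value).lower() in ("true", "1", "1.0", "yes", "active"):
            out.append(_ev("flowsheets", r, "heart failure on problem list"))
    return out


def _ckd(adm, cohort, p):
    out = []
    black = adm.race_ethnicity == "Black"
    for r in _enc_labs(adm, cohort, "serum_creatinine"):
        if r.numeric_value is None or r.numeric_value <= 0 or adm.age_years <= 0:
            continue
        egfr = egfr_mdrd(r.numeric_value, adm.age_years, adm.sex, black)
        if egfr <= p.egfr_max:
            out.append(_ev("labs", r, f"MDRD eGFR {egfr:.1f}"))
    return out


def _delirium(adm, cohort, p):
    return [_ev("flowsheets", r, "positive CAM")
            for r in cohort.encounter_records("flowsheets", adm.encounter_id)
            if r.measure == "CAM_result"
            and str(r.value).lower() in ("positive", "true", "1", "1.0")]


def _extreme_bmi(adm, cohort, p):
    return [_ev("flowsheets", r, f"BMI {r.value}")
            for r in cohort.encounter_records("flowsheets", adm.encounter_id)
            if r.measure == "BMI" and isinstance(r.value, float)
            and (r.value > p.bmi_high or r.value < p.bmi_low)]


def _hiv(adm, cohort, p):
    hi = to_days(adm.discharge_time)
    out = [_ev("labs", r, "positive HIV screen")
           for r in cohort.patient_records("labs", adm.patient_id)
           if r.analyte == "HIV_screen" and r.abnormal_flag == "positive"
           and to_days(r.collected_time) <= hi]
    out += [_ev("medications", r, "active zidovudine")
            for r in cohort.encounter_records("medications", adm.encounter_id)
            if r.drug == "zidovudine" and r.event_kind == "order_active"]
    return out


def _hyponatremia(adm, cohort, p):
    return [_ev("labs", r, f"sodium {r.numeric_value} mmol/L")
            for r in _enc_labs(adm, cohort, "sodium")
            if r.numeric_value is not None and r.numeric_value <= p.sodium_max]


def _positive_troponins(adm, cohort, p):
    return [r for r in _enc_labs(adm, cohort, "troponin")
            if r.abnormal_flag == p.troponin_positive_flag]


def _myocardial_injury(adm, cohort, p):
    return [_ev("labs", r, "positive troponin")
            for r in _positive_troponins(adm, cohort, p)]


def _transplant(adm, cohort, p):
    hi = to_days(adm.discharge_time)
    out = [_ev("procedures", r, "transplant surgery")
           for r in cohort.patient_records("procedures", adm.patient_id)
           if r.kind == "transplant_surgery" and to_days(r.event_time) <= hi]
    out += [_ev("medications", r, "tacrolimus administration")
            for r in cohort.encounter_records("medications", adm.encounter_id)
            if r.drug == "tacrolimus" and r.event_kind == "administration"]
    return out


def _uti(adm, cohort, p):
    return [_ev("cultures", r, f"urine culture {r.colony_count:.0f} CFU/mL")
            for r in cohort.encounter_records("cultures", adm.encounter_id)
            if r.specimen == "urine" and r.colony_count is not None
            and r.colony_count >= p.urine_colony_min]


def _acute_mi(adm, cohort, p):
    trops = _positive_troponins(adm, cohort, p)
    stents = [r for r in cohort.encounter_records("procedures", adm.encounter_id)
              if r.kind == "coronary_stent"]
    if trops and stents:
        return ([_ev("labs", r, "positive troponin") for r in trops]
                + [_ev("procedures", r, "coronary stent") for r in stents])
    return []


def _pancreatitis(adm, cohort, p):
    out = [_ev("labs", r, f"amylase {r.numeric_value} U/L")
           for r in _enc_labs(adm, cohort, "amylase")
           if r.numeric_value is not None and r.numeric_value > p.amylase_min]
    out += [_ev("labs", r, f"lipase {r.numeric_value} U/L")
            for r in _enc_labs(adm, cohort, "lipase")
            if r.numeric_value is not None and r.numeric_value > p.lipase_min]
    return out


def _altered_mental_status(adm, cohort, p):
    return [_ev("flowsheets", r, f"GCS {r.value}")
            for r in cohort.encounter_records("flowsheets", adm.encounter_id)
            if r.measure == "GCS_total" and isinstance(r.value, float)
            and r.value <= p.gcs_max]


def _esrd(adm, cohort, p):
    return [_ev("flowsheets", r, "dialysis flow documented")
            for r in cohort.encounter_records("flowsheets", adm.encounter_id)
            if r.measure == "dialysis_flow"]


def _inpatient_death(adm, cohort, p):
    if adm.died_inpatient:
        return [Evidence("admissions", adm.encounter_id, "inpatient death")]
    return []


def _respiratory_failure(adm, cohort, p):
    devices = [r for r in cohort.encounter_records("flowsheets", adm.encounter_id)
               if r.measure == "airway_device" and str(r.value) in p.airway_devices]
    # exclusion: any OR case during the index admission disqualifies
    surgeries = [r for r in cohort.encounter_records("procedures", adm.encounter_id)
                 if r.kind == "surgery_case"]
    if devices and not surgeries:
        return [_ev("flowsheets", r, f"airway device {r.value}") for r in devices]
    return []


def _malnutrition(adm, cohort, p):
    return [_ev("medications", r, "TPN documented")
            for r in cohort.encounter_records("medications", adm.encounter_id)
            if r.drug == "TPN"]


# ---------------------------------------------------------------------------
# Rulebook
# ---------------------------------------------------------------------------

_RULE_SPECS: list[tuple[str, str, tuple[str, ...], Callable]] = [
    ("Acidemia", CC, ("E71.*", "E87.2", "E72.*"), _acidemia),
    ("Bacteremia", CC, ("R78.81", "R65.10"), _bacteremia),
    ("Blood Loss Anemia", CC, ("D62",), _blood_loss_anemia),
    ("Chronic CHF", CC, ("I50.*",), _chronic_chf),
    ("Chronic Kidney Disease", CC, ("N18.4", "N18.5", "N18.8", "N18.9"), _ckd),
    ("Delirium", CC, ("F05", "R41.4", "R40.3"), _delirium),
    ("Extremes of BMI", CC, ("E66.2", "Z68.1", "Z68.4", "R64"), _extreme_bmi),
    ("HIV", CC, ("B20",), _hiv),
    ("Hyponatremia", CC, ("E87.1",), _hyponatremia),
    ("Myocardial Injury", CC, ("S26.90XA", "I25.*", "I24.8", "I24.9"),
     _myocardial_injury),
    ("Transplant", CC, ("T86.*", "Z94.*"), _transplant),
    ("UTI", CC, ("N39.0", "O23.40", "O23.41", "O86.2", "O03.38", "O04.88",
                 "O08.83", "O23.42", "O23.43"), _uti),
    ("Acute MI", MCC, ("I21.*", "I22.*"), _acute_mi),
    ("Acute Pancreatitis", MCC, ("K85.*",), _pancreatitis),
    ("Altered Mental Status", MCC, ("R40.*",), _altered_mental_status),
    ("End Stage Renal Disease", MCC, ("N18.6", "N17.0", "N17.1"), _esrd),
    ("Inpatient Death", MCC, (), _inpatient_death),
    ("Respiratory Failure", MCC, ("J96.*", "J95.*"), _respiratory_failure),
    ("Severe Malnutrition", MCC, ("E40.*", "E41.*", "E42.*", "E43.*"),
     _malnutrition),
]

DISEASES = tuple(name for name, *_ in _RULE_SPECS)
DISEASE_LEVEL = {name: level for name, level, *_ in _RULE_SPECS}


def build_rulebook(params: Optional[RuleParams] = None) -> list[PhenotypeRule]:
    """The 19 shipped disease rules (12 CC-tier, 7 MCC-tier)."""
    del params  # thresholds are applied at evaluation time
    return [PhenotypeRule(name, level, patterns, pred)
            for name, level, patterns, pred in _RULE_SPECS]


def evaluate_rule(rule: PhenotypeRule, admission: AdmissionRecord,
                  cohort: Cohort,
                  params: Optional[RuleParams] = None) -> PhenotypeCall:
    params = params or RuleParams()
    evidence = rule.predicate(admission, cohort, params)
    evidence = sorted(set(evidence), key=lambda e: (e.table, e.locator, e.detail))
    return PhenotypeCall(admission.encounter_id, rule.disease_name,
                         bool(evidence), evidence)


def evaluate_cohort(rulebook: Sequence[PhenotypeRule], cohort: Cohort,
                    params: Optional[RuleParams] = None) -> list[PhenotypeCall]:
    """One call per admission x rule, in deterministic order."""
    params = params or RuleParams()
    calls = []
    for adm in cohort.admissions:
        for rule in rulebook:
            calls.append(evaluate_rule(rule, adm, cohort, params))
    return calls
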