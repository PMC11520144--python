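"""Seeded synthetic EHR cohort generator.

Emulates the structure of a one-year academic-hospital admission cohort so the
whole audit pipeline (phenotyping -> omission flagging -> DRG upgrade ->
revenue -> statistics) runs without any data download. Per admission the
generator draws latent disease states from per-disease prevalences, injects
rule-satisfying clinical records for true diseases (values sampled just past
each threshold) and strictly safe-side records for a random subset of false
diseases, emits a qualifying ICD code with probability 1 - omission rate, and
bills a DRG at or below the justified severity tier under a configurable
under-coding scheme. The hidden labels are returned as a
:class:`LatentTruth` answer key that the pipeline must reproduce exactly.

Default prevalences, omission rates, payor/sex/race/age mixes and the Singlet
DRG fraction mirror the published rates of a ~34,000-admission audit cohort.

Two latent-truth closure rules keep the answer key consistent with the
injected evidence: an acute MI (positive troponin + stent) necessarily also
satisfies the myocardial-injury rule, and a blood-loss-anemia admission
carries an OR case, which disqualifies the respiratory-failure rule's
no-surgery requirement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .audit import UpgradeType, upgrade_type_for
from .model import (AdmissionRecord, Cohort, CultureResult,
                    FlowsheetObservation, LabResult, MedicationEvent,
                    ProcedureEvent)
from .phenotypes import DISEASES, DISEASE_LEVEL, _RULE_SPECS
from .revenue import PayorClass

logger = logging.getLogger(__name__)

DISEASE_RANK = {d: (2 if lvl == "MCC" else 1) for d, lvl in DISEASE_LEVEL.items()}
HAS_PATTERNS = {name: bool(pats) for name, _, pats, _ in _RULE_SPECS}

# one canonical billable code per disease; chosen so no code matches another
# disease's qualifying patterns
EMIT_CODE = {
    "Acidemia": "E87.2",
    "Bacteremia": "R78.81",
    "Blood Loss Anemia": "D62",
    "Chronic CHF": "I50.9",
    "Chronic Kidney Disease": "N18.4",
    "Delirium": "F05",
    "Extremes of BMI": "E66.2",
    "HIV": "B20",
    "Hyponatremia": "E87.1",
    "Myocardial Injury": "I25.9",
    "Transplant": "Z94.0",
    "UTI": "N39.0",
    "Acute MI": "I21.9",
    "Acute Pancreatitis": "K85.9",
    "Altered Mental Status": "R40.2",
    "End Stage Renal Disease": "N18.6",
    "Respiratory Failure": "J96.0",
    "Severe Malnutrition": "E43",
}

# prevalence and ICD-omission defaults: per-disease detected-admission rates
# and missing-code fractions of a published 34,104-admission audit year
DEFAULT_PREVALENCE = {
    "Acidemia": 0.0719, "Acute MI": 0.0009, "Bacteremia": 0.0227,
    "Blood Loss Anemia": 0.0334, "Chronic CHF": 0.0400,
    "Chronic Kidney Disease": 0.1268, "Delirium": 0.0208,
    "Extremes of BMI": 0.1153, "HIV": 0.0088, "Hyponatremia": 0.2865,
    "Myocardial Injury": 0.0771, "Transplant": 0.0821, "UTI": 0.0606,
    "Acute Pancreatitis": 0.0066, "Altered Mental Status": 0.1014,
    "End Stage Renal Disease": 0.0158, "Inpatient Death": 0.0277,
    "Respiratory Failure": 0.0250, "Severe Malnutrition": 0.0233,
}

DEFAULT_OMISSION = {
    "Acidemia": 0.632, "Acute MI": 0.125, "Bacteremia": 0.252,
    "Blood Loss Anemia": 0.267, "Chronic CHF": 0.215,
    "Chronic Kidney Disease": 0.245, "Delirium": 0.803,
    "Extremes of BMI": 0.468, "HIV": 0.070, "Hyponatremia": 0.623,
    "Myocardial Injury": 0.371, "Transplant": 0.040, "UTI": 0.291,
    "Acute Pancreatitis": 0.200, "Altered Mental Status": 0.496,
    "End Stage Renal Disease": 0.160, "Inpatient Death": 0.0,
    "Respiratory Failure": 0.039, "Severe Malnutrition": 0.579,
}

DEFAULT_PAYOR_MIX = {"MEDI-CAL": 0.140, "MEDICARE": 0.383, "PRIVATE": 0.477}
DEFAULT_SEX_MIX = {"male": 0.461, "female": 0.539}
DEFAULT_RACE_MIX = {
    "Asian/Pacific Islander": 0.0975, "Black": 0.0977,
    "Caucasian-Hispanic": 0.0764, "Caucasian-Non-Hispanic": 0.5106,
    "Other-Hispanic": 0.1312, "Other-Non-Hispanic": 0.0866,
}
DEFAULT_AGE_MIX = {
    "18-35 (young adult)": 0.2081, "36-64 (middle age)": 0.4072,
    "65-78 (aged)": 0.2358, "79+ (old)": 0.1489,
}

_AGE_RANGES = {
    "18-35 (young adult)": (18.0, 36.0),
    "36-64 (middle age)": (36.0, 65.0),
    "65-78 (aged)": (65.0, 79.0),
    "79+ (old)": (79.0, 96.0),
}

_RAW_PAYORS = {
    "MEDI-CAL": ("Medi-Cal", "Medicaid"),
    "MEDICARE": ("Medicare", "Medicare Advantage"),
    "PRIVATE": ("Blue Shield PPO", "Commercial HMO", "Self-Pay"),
}


class FamilySpec(BaseModel):
    """A leveled DRG family: base < CC < MCC relative weights."""
    name: str
    rwf_base: float
    rwf_cc: float
    rwf_mcc: float

    @model_validator(mode="after")
    def _increasing(self):
        if not 0 < self.rwf_base < self.rwf_cc < self.rwf_mcc:
            raise ValueError(f"family {self.name}: RWF must be strictly "
                             "increasing base < CC < MCC")
        return self


DEFAULT_FAMILIES = [
    FamilySpec(name="SEPTICEMIA OR SEVERE SEPSIS", rwf_base=1.0422, rwf_cc=1.3858, rwf_mcc=1.8722),
    FamilySpec(name="PLEURAL EFFUSION", rwf_base=0.8255, rwf_cc=1.0021, rwf_mcc=1.4378),
    FamilySpec(name="HEART FAILURE AND SHOCK", rwf_base=0.6762, rwf_cc=0.9680, rwf_mcc=1.4290),
    FamilySpec(name="RENAL FAILURE", rwf_base=0.6187, rwf_cc=0.9344, rwf_mcc=1.4113),
    FamilySpec(name="SIMPLE PNEUMONIA AND PLEURISY", rwf_base=0.7044, rwf_cc=0.8724, rwf_mcc=1.3167),
    FamilySpec(name="KIDNEY AND URINARY TRACT INFECTIONS", rwf_base=0.5965, rwf_cc=0.7825, rwf_mcc=1.1255),
    FamilySpec(name="NUTRITIONAL AND MISC METABOLIC DISORDERS", rwf_base=0.5541, rwf_cc=0.7367, rwf_mcc=1.1755),
    FamilySpec(name="CELLULITIS", rwf_base=0.6082, rwf_cc=0.8067, rwf_mcc=1.2042),
    FamilySpec(name="CARDIAC ARRHYTHMIA AND CONDUCTION DISORDERS", rwf_base=0.5573, rwf_cc=0.7509, rwf_mcc=1.1216),
    FamilySpec(name="DIABETES", rwf_base=0.5668, rwf_cc=0.7408, rwf_mcc=1.1035),
    FamilySpec(name="GI HEMORRHAGE", rwf_base=0.7157, rwf_cc=0.9971, rwf_mcc=1.5530),
    FamilySpec(name="ESOPHAGITIS AND MISC DIGESTIVE DISORDERS", rwf_base=0.5816, rwf_cc=0.7473, rwf_mcc=1.1902),
]

DEFAULT_SINGLETS = [("HEART TRANSPLANT", 26.2839),
                    ("TRACHEOSTOMY FOR FACE MOUTH AND NECK DIAGNOSES", 3.5513)]


class SynthConfig(BaseModel):
    """Generator parameters; every default reflects the emulated cohort."""

    n_admissions: int = Field(500, gt=0)
    seed: int = 0
    disease_prevalence: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    icd_omission_rate: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_OMISSION))
    undercode_prob: float = Field(0.10, ge=0, le=0.5)
    noise_rate: float = Field(0.20, ge=0, le=1)          # safe-side records per false disease
    nonspecific_code_rate: float = Field(0.02, ge=0, le=1)  # codes without clinical criteria
    drg_families: list[FamilySpec] = Field(default_factory=lambda: list(DEFAULT_FAMILIES))
    singlet_drgs: list[tuple[str, float]] = Field(default_factory=lambda: list(DEFAULT_SINGLETS))
    singlet_fraction: float = Field(0.108, ge=0, le=1)
    payor_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PAYOR_MIX))
    sex_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_SEX_MIX))
    race_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    age_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_AGE_MIX))
    icd_padding: Optional[int] = Field(None, gt=0)       # pad code lists to this length

    @field_validator("disease_prevalence", "icd_omission_rate")
    @classmethod
    def _fractions(cls, v):
        for name, frac in v.items():
            if name not in DISEASES:
                raise ValueError(f"unknown disease {name!r}")
            if not 0 <= frac <= 1:
                raise ValueError(f"{name}: fraction {frac} outside [0,1]")
        return v

    @field_validator("payor_mix", "sex_mix", "race_mix", "age_mix")
    @classmethod
    def _sums_to_one(cls, v):
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix sums to {total}, expected 1")
        return v

    @model_validator(mode="after")
    def _feasible(self):
        if not self.drg_families:
            raise ValueError("at least one leveled DRG family is required")
        if self.singlet_fraction > 0 and not self.singlet_drgs:
            raise ValueError("singlet_fraction > 0 but no singlet DRGs configured")
        return self


def demo_catalogue_frame(config: Optional[SynthConfig] = None) -> pd.DataFrame:
    """CMS-style mini catalogue (drg_code, description, rwf) for the config's
    DRG families: three leveled arms per family plus the Singlet entries."""
    config = config or SynthConfig()
    rows = []
    for i, fam in enumerate(config.drg_families):
        base_code = 100 + 3 * i
        rows.append({"drg_code": str(base_code), "description": f"{fam.name} WITH MCC", "rwf": fam.rwf_mcc})
        rows.append({"drg_code": str(base_code + 1), "description": f"{fam.name} WITH CC", "rwf": fam.rwf_cc})
        rows.append({"drg_code": str(base_code + 2), "description": f"{fam.name} WITHOUT CC/MCC", "rwf": fam.rwf_base})
    for j, (name, rwf) in enumerate(config.singlet_drgs):
        rows.append({"drg_code": str(j + 1).zfill(3), "description": name, "rwf": rwf})
    return pd.DataFrame(rows)


@dataclass
class AdmissionTruth:
    """Hidden labels for one synthetic admission."""
    encounter_id: str
    patient_id: str
    diseases: frozenset
    icd_emitted: dict          # disease -> bool, for true diseases with codes
    nonspecific_codes: frozenset  # false diseases whose code was still billed
    required_rank: int         # 0 base, 1 CC, 2 MCC
    billed_drg_code: str
    billed_rank: Optional[int]  # None when the billed DRG is a Singlet
    is_singlet: bool
    expected_upgrade_type: UpgradeType
    expected_target_code: Optional[str]
    expected_delta_rwf: float
    payor: PayorClass


@dataclass
class LatentTruth:
    config: SynthConfig
    admissions: list[AdmissionTruth] = field(default_factory=list)


@dataclass(frozen=True)
class ExpectedFinding:
    encounter_id: str
    disease_name: str
    detected: bool
    icd_present: bool
    missing_icd: bool


@dataclass(frozen=True)
class ExpectedUpgrade:
    encounter_id: str
    upgrade_type: UpgradeType
    target_drg_code: Optional[str]
    delta_rwf: float
    driving_diseases: frozenset


def truth_table(latent: LatentTruth) -> tuple[list[ExpectedFinding],
                                              dict[str, ExpectedUpgrade]]:
    """The answer key the pipeline must reproduce on noiseless synthetic data."""
    findings = []
    flags = {}
    for t in latent.admissions:
        for d in DISEASES:
            detected = d in t.diseases
            present = bool(t.icd_emitted.get(d, False)) or d in t.nonspecific_codes
            findings.append(ExpectedFinding(
                t.encounter_id, d, detected, present,
                detected and not present and HAS_PATTERNS[d]))
        driving = frozenset(
            d for d in t.diseases
            if t.billed_rank is not None and DISEASE_RANK[d] > t.billed_rank)
        flags[t.encounter_id] = ExpectedUpgrade(
            t.encounter_id, t.expected_upgrade_type, t.expected_target_code,
            t.expected_delta_rwf,
            driving if t.expected_upgrade_type is not UpgradeType.NONE
            else frozenset())
    return findings, flags


# ---------------------------------------------------------------------------
# Record injection
# ---------------------------------------------------------------------------

def _mdrd_threshold_creatinine(age: float, sex: str, black: bool,
                               egfr_cut: float = 30.0) -> float:
    """Creatinine at which the MDRD eGFR equals the cut-off."""
    f = 0.742 if sex == "female" else 1.0
    f *= 1.212 if black else 1.0
    return (175.0 * age ** -0.203 * f / egfr_cut) ** (1.0 / 1.154)


class _Injector:
    """Writes clinical records for one admission into the growing cohort."""

    def __init__(self, cohort: Cohort, adm: AdmissionRecord,
                 rng: np.random.Generator):
        self.c = cohort
        self.a = adm
        self.rng = rng

    def _t(self) -> datetime:
        lo = self.a.admit_time
        span = (self.a.discharge_time - lo).total_seconds()
        return lo + timedelta(seconds=float(self.rng.uniform(0, span)))

    def _t_lookback(self, max_days: float = 364.0) -> datetime:
        return self.a.admit_time - timedelta(days=float(self.rng.uniform(1, max_days)))

    def lab(self, analyte, value=None, flag=None, when=None, patient_level=False):
        self.c.labs.append(LabResult(
            collected_time=when or self._t(), analyte=analyte,
            encounter_id=None if patient_level else self.a.encounter_id,
            patient_id=self.a.patient_id if patient_level else None,
            numeric_value=None if value is None else float(value),
            abnormal_flag=flag))

    def flow(self, measure, value, when=None, patient_level=False):
        self.c.flowsheets.append(FlowsheetObservation(
            observed_time=when or self._t(), measure=measure, value=value,
            encounter_id=None if patient_level else self.a.encounter_id,
            patient_id=self.a.patient_id if patient_level else None))

    def culture(self, specimen, positive, colonies=None, when=None):
        self.c.cultures.append(CultureResult(
            encounter_id=self.a.encounter_id, collected_time=when or self._t(),
            specimen=specimen, positive=positive,
            colony_count=None if colonies is None else float(colonies)))

    def med(self, drug, kind, when=None):
        self.c.medications.append(MedicationEvent(
            event_time=when or self._t(), drug=drug, event_kind=kind,
            encounter_id=self.a.encounter_id))

    def proc(self, kind, when=None, patient_level=False):
        self.c.procedures.append(ProcedureEvent(
            event_time=when or self._t(), kind=kind,
            encounter_id=None if patient_level else self.a.encounter_id,
            patient_id=self.a.patient_id if patient_level else None))

    # ---- positive evidence, sampled just past each threshold ----

    def positive(self, disease: str) -> None:
        rng = self.rng
        if disease == "Acidemia":
            self.lab("arterial_pH", rng.uniform(7.20, 7.349))
        elif disease == "Bacteremia":
            for _ in range(int(rng.integers(2, 4))):
                self.culture("blood", True)
        elif disease == "Blood Loss Anemia":
            t_surg = self._t()
            self.proc("surgery_case", when=t_surg)
            self.flow("intraop_blood_loss_mL", float(rng.uniform(300, 1500)), when=t_surg)
            self.lab("hemoglobin", rng.uniform(7.0, 11.9),
                     when=t_surg + timedelta(hours=float(rng.uniform(1, 23))))
        elif disease == "Chronic CHF":
            branch = rng.integers(0, 3)
            if branch == 0:
                self.flow("ejection_fraction", float(rng.uniform(10, 30)),
                          when=self._t_lookback(), patient_level=True)
            elif branch == 1:
                self.lab("BNP", rng.uniform(901, 4000),
                         when=self._t_lookback(), patient_level=True)
            else:
                self.flow("problem_list_heart_failure", "true",
                          when=self._t_lookback(), patient_level=True)
        elif disease == "Chronic Kidney Disease":
            cut = _mdrd_threshold_creatinine(
                self.a.age_years, self.a.sex, self.a.race_ethnicity == "Black")
            self.lab("serum_creatinine", cut * rng.uniform(1.05, 2.5))
        elif disease == "Delirium":
            self.flow("CAM_result", "positive")
        elif disease == "Extremes of BMI":
            self.flow("BMI", float(rng.uniform(40.1, 55) if rng.random() < 0.5
                                   else rng.uniform(12, 18.9)))
        elif disease == "HIV":
            if rng.random() < 0.5:
                self.lab("HIV_screen", flag="positive",
                         when=self._t_lookback(3000), patient_level=True)
            else:
                self.med("zidovudine", "order_active")
        elif disease == "Hyponatremia":
            self.lab("sodium", rng.uniform(120, 134))
        elif disease == "Myocardial Injury":
            self.lab("troponin", rng.uniform(0.1, 5), flag="positive")
        elif disease == "Transplant":
            if rng.random() < 0.5:
                self.proc("transplant_surgery", when=self._t_lookback(3000),
                          patient_level=True)
            else:
                self.med("tacrolimus", "administration")
        elif disease == "UTI":
            self.culture("urine", True, colonies=rng.uniform(1e5, 5e5))
        elif disease == "Acute MI":
            self.lab("troponin", rng.uniform(0.5, 10), flag="positive")
            self.proc("coronary_stent")
        elif disease == "Acute Pancreatitis":
            if rng.random() < 0.5:
                self.lab("amylase", rng.uniform(1001, 3000))
            else:
                self.lab("lipase", rng.uniform(451, 2000))
        elif disease == "Altered Mental Status":
            self.flow("GCS_total", float(rng.integers(3, 9)))
        elif disease == "End Stage Renal Disease":
            self.flow("dialysis_flow", float(rng.uniform(200, 400)))
        elif disease == "Respiratory Failure":
            self.flow("airway_device",
                      str(rng.choice(["endotracheal_tube", "high_flow_nasal_cannula"])))
        elif disease == "Severe Malnutrition":
            self.med("TPN", "administration")
        # Inpatient Death carries no clinical record: the admission flag is it

    # ---- safe-side noise, strictly on the negative side of every rule ----

    def negative(self, disease: str, truth: frozenset) -> None:
        rng = self.rng
        if disease == "Acidemia":
            self.lab("arterial_pH", rng.uniform(7.36, 7.45))
        elif disease == "Bacteremia":
            if rng.random() < 0.5:
                self.culture("blood", True)   # a single positive never qualifies
            else:
                self.culture("blood", False)
        elif disease == "Blood Loss Anemia":
            t_surg = self._t()
            if "Respiratory Failure" not in truth:
                self.proc("surgery_case", when=t_surg)
            self.flow("intraop_blood_loss_mL", float(rng.uniform(50, 299)), when=t_surg)
            self.lab("hemoglobin", rng.uniform(12.1, 15.5),
                     when=t_surg + timedelta(hours=float(rng.uniform(1, 23))))
        elif disease == "Chronic CHF":
            self.flow("ejection_fraction", float(rng.uniform(35, 65)),
                      when=self._t_lookback(), patient_level=True)
        elif disease == "Chronic Kidney Disease":
            cut = _mdrd_threshold_creatinine(
                self.a.age_years, self.a.sex, self.a.race_ethnicity == "Black")
            self.lab("serum_creatinine", max(cut * rng.uniform(0.3, 0.95), 0.3))
        elif disease == "Delirium":
            self.flow("CAM_result", "negative")
        elif disease == "Extremes of BMI":
            self.flow("BMI", float(rng.uniform(19.5, 39.5)))
        elif disease == "HIV":
            self.lab("HIV_screen", flag="negative")
        elif disease == "Hyponatremia":
            self.lab("sodium", rng.uniform(135, 145))
        elif disease == "Myocardial Injury":
            self.lab("troponin", rng.uniform(0.0, 0.03), flag="normal")
        elif disease == "Transplant":
            self.med("tacrolimus", "order_active")  # order without administration
        elif disease == "UTI":
            self.culture("urine", rng.random() < 0.5, colonies=rng.uniform(1e3, 9.9e4))
        elif disease == "Acute MI":
            if "Myocardial Injury" not in truth:
                self.proc("coronary_stent")  # stent without positive troponin
        elif disease == "Acute Pancreatitis":
            if rng.random() < 0.5:
                self.lab("amylase", rng.uniform(30, 1000))
            else:
                self.lab("lipase", rng.uniform(10, 450))
        elif disease == "Altered Mental Status":
            self.flow("GCS_total", float(rng.integers(9, 16)))
        elif disease == "Respiratory Failure":
            self.flow("airway_device", "nasal_cannula")
        # ESRD, Severe Malnutrition, Inpatient Death: presence-defined,
        # absence of the record is the negative


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _choice(rng, mapping: dict):
    keys = list(mapping)
    probs = np.asarray([mapping[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def generate_cohort(config: Optional[SynthConfig] = None,
                    seed: Optional[int] = None) -> tuple[Cohort, LatentTruth]:
    """Deterministically generate a cohort and its hidden answer key."""
    config = config or SynthConfig()
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    rng = np.random.default_rng(config.seed)
    cohort = Cohort()
    latent = LatentTruth(config)

    fam_codes = {}  # family index -> {rank: (code, rwf)}
    for i, fam in enumerate(config.drg_families):
        base = 100 + 3 * i
        fam_codes[i] = {0: (str(base + 2), fam.rwf_base),
                        1: (str(base + 1), fam.rwf_cc),
                        2: (str(base), fam.rwf_mcc)}
    singlet_codes = [(str(j + 1).zfill(3), rwf)
                     for j, (_, rwf) in enumerate(config.singlet_drgs)]

    year_start = datetime(2019, 1, 1)
    u = config.undercode_prob

    for i in range(config.n_admissions):
        enc, pid = f"E{i:06d}", f"P{i:06d}"
        sex = _choice(rng, config.sex_mix)
        race = _choice(rng, config.race_mix)
        band = _choice(rng, config.age_mix)
        lo, hi = _AGE_RANGES.get(band, (18.0, 90.0))
        age = float(rng.uniform(lo, hi - 1e-6))
        payor_name = _choice(rng, config.payor_mix)
        raw_payor = str(rng.choice(_RAW_PAYORS[payor_name]))
        admit = year_start + timedelta(days=float(rng.uniform(0, 364)))
        discharge = admit + timedelta(days=float(rng.uniform(1, 14)))

        truth_set = {d for d in DISEASES
                     if rng.random() < config.disease_prevalence.get(d, 0.0)}
        # closure: keep the answer key consistent with injected evidence
        if "Acute MI" in truth_set:
            truth_set.add("Myocardial Injury")
        if "Blood Loss Anemia" in truth_set:
            truth_set.discard("Respiratory Failure")
        truth = frozenset(truth_set)

        adm = AdmissionRecord(
            encounter_id=enc, patient_id=pid, admit_time=admit,
            discharge_time=discharge,
            died_inpatient="Inpatient Death" in truth,
            raw_financial_class=raw_payor, sex=sex, race_ethnicity=race,
            age_years=age)
        inj = _Injector(cohort, adm, rng)

        for d in DISEASES:
            if d in truth:
                inj.positive(d)
            elif rng.random() < config.noise_rate:
                inj.negative(d, truth)

        icd_emitted: dict[str, bool] = {}
        nonspecific = set()
        codes: list[str] = []
        for d in DISEASES:
            if not HAS_PATTERNS[d]:
                continue
            if d in truth:
                emitted = rng.random() >= config.icd_omission_rate.get(d, 0.0)
                icd_emitted[d] = emitted
                if emitted:
                    codes.append(EMIT_CODE[d])
            elif rng.random() < config.nonspecific_code_rate:
                nonspecific.add(d)
                codes.append(EMIT_CODE[d])
        if config.icd_padding:
            k = 0
            while len(codes) < config.icd_padding:
                codes.append(f"Y9{2 + k // 10}.{k % 10}")
                k += 1
        adm.billed_icd_codes = codes

        required = max((DISEASE_RANK[d] for d in truth), default=0)
        if rng.random() < config.singlet_fraction:
            code, _rwf = singlet_codes[int(rng.integers(len(singlet_codes)))]
            t = AdmissionTruth(enc, pid, truth, icd_emitted,
                               frozenset(nonspecific), required, code, None,
                               True, UpgradeType.NONE, None, 0.0,
                               PayorClass(payor_name))
        else:
            fam_i = int(rng.integers(len(config.drg_families)))
            weights = np.array([1.0 - u - u * u / 2, u, u * u / 2])[: required + 1]
            steps = int(rng.choice(len(weights), p=weights / weights.sum()))
            billed_rank = required - steps
            billed_code, billed_rwf = fam_codes[fam_i][billed_rank]
            if required > billed_rank:
                target_code, target_rwf = fam_codes[fam_i][required]
                t = AdmissionTruth(
                    enc, pid, truth, icd_emitted, frozenset(nonspecific),
                    required, billed_code, billed_rank, False,
                    upgrade_type_for(billed_rank, required), target_code,
                    target_rwf - billed_rwf, PayorClass(payor_name))
            else:
                t = AdmissionTruth(enc, pid, truth, icd_emitted,
                                   frozenset(nonspecific), required,
                                   billed_code, billed_rank, False,
                                   UpgradeType.NONE, None, 0.0,
                                   PayorClass(payor_name))
        adm.billed_drg_code = t.billed_drg_code
        cohort.admissions.append(adm)
        latent.admissions.append(t)

    cohort.reindex()
    return cohort, latent


def truth_to_frame(latent: LatentTruth) -> pd.DataFrame:
    """Flat answer-key table (written as truth.csv next to the cohort)."""
    rows = []
    for t in latent.admissions:
        omitted = sorted(d for d, e in t.icd_emitted.items() if not e)
        rows.append({
            "encounter_id": t.encounter_id,
            "diseases": ";".join(sorted(t.diseases)),
            "omitted_icd": ";".join(omitted),
            "nonspecific_codes": ";".join(sorted(t.nonspecific_codes)),
            "required_rank": t.required_rank,
            "billed_drg_code": t.billed_drg_code,
            "billed_is_singlet": t.is_singlet,
            "expected_upgrade_type": t.expected_upgrade_type.value,
            "expected_target_code": t.expected_target_code or "",
            "expected_delta_rwf": t.expected_delta_rwf,
            "payor": t.payor.value,
        })
    return pd.DataFrame(rows)
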