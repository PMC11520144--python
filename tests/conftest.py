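from datetime import datetime, timedelta

import pytest

from drgaudit.audit import build_catalogue
from drgaudit.model import (AdmissionRecord, Cohort, CultureResult,
                            FlowsheetObservation, LabResult, MedicationEvent,
                            ProcedureEvent)
from drgaudit.synth import SynthConfig, demo_catalogue_frame, generate_cohort

ADMIT = datetime(2019, 3, 1, 8, 0)
DISCHARGE = datetime(2019, 3, 6, 12, 0)


def make_admission(enc="E1", pid="P1", admit=ADMIT, discharge=DISCHARGE,
                   died=False, payor="Blue Shield PPO", sex="female",
                   race="Caucasian-Non-Hispanic", age=55.0, codes=(),
                   drg=None) -> AdmissionRecord:
    return AdmissionRecord(enc, pid, admit, discharge, died, payor, sex, race,
                           age, list(codes), drg)


def lab(enc="E1", analyte="sodium", value=None, flag=None, when=None, pid=None):
    return LabResult(collected_time=when or ADMIT + timedelta(hours=6),
                     analyte=analyte, encounter_id=enc, patient_id=pid,
                     numeric_value=value, abnormal_flag=flag)


def flow(enc="E1", measure="BMI", value=25.0, when=None, pid=None):
    return FlowsheetObservation(observed_time=when or ADMIT + timedelta(hours=4),
                                measure=measure, value=value,
                                encounter_id=enc, patient_id=pid)


def culture(enc="E1", specimen="blood", positive=True, colonies=None, when=None):
    return CultureResult(encounter_id=enc,
                         collected_time=when or ADMIT + timedelta(hours=9),
                         specimen=specimen, positive=positive,
                         colony_count=colonies)


def med(enc="E1", drug="TPN", kind="administration", when=None):
    return MedicationEvent(event_time=when or ADMIT + timedelta(hours=12),
                           drug=drug, event_kind=kind, encounter_id=enc)


def proc(enc="E1", kind="surgery_case", when=None, pid=None):
    return ProcedureEvent(event_time=when or ADMIT + timedelta(days=1),
                          kind=kind, encounter_id=enc, patient_id=pid)


def single_admission_cohort(records=(), **adm_kwargs) -> Cohort:
    """One admission plus the given clinical records, sorted into tables."""
    cohort = Cohort(admissions=[make_admission(**adm_kwargs)])
    for rec in records:
        if isinstance(rec, LabResult):
            cohort.labs.append(rec)
        elif isinstance(rec, CultureResult):
            cohort.cultures.append(rec)
        elif isinstance(rec, FlowsheetObservation):
            cohort.flowsheets.append(rec)
        elif isinstance(rec, MedicationEvent):
            cohort.medications.append(rec)
        elif isinstance(rec, ProcedureEvent):
            cohort.procedures.append(rec)
        else:
            raise TypeError(type(rec))
    return cohort


@pytest.fixture(scope="session")
def mini_catalogue():
    return build_catalogue(demo_catalogue_frame())


@pytest.fixture(scope="session")
def small_synth():
    """A 120-admission synthetic cohort with its answer key (seeded)."""
    return generate_cohort(SynthConfig(n_admissions=120, seed=11))
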