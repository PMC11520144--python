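"""Phenotype rulebook: thresholds, windows, and whole-cohort evaluation."""
import random
from datetime import timedelta

import pytest

from conftest import (ADMIT, culture, flow, lab, make_admission, med, proc,
                      single_admission_cohort)
from drgaudit.model import Cohort
from drgaudit.phenotypes import (DISEASES, DISEASE_LEVEL, build_rulebook,
                                 egfr_mdrd, evaluate_cohort, evaluate_rule,
                                 within_window)
from reference_impl import naive_evaluate

RULES = {r.disease_name: r for r in build_rulebook()}


def detect(disease, records=(), **adm_kwargs) -> bool:
    cohort = single_admission_cohort(records, **adm_kwargs)
    call = evaluate_rule(RULES[disease], cohort.admissions[0], cohort)
    assert call.detected == bool(call.evidence)
    return call.detected


class TestRulebook:
    def test_nineteen_rules_twelve_cc_seven_mcc(self):
        rules = build_rulebook()
        assert len(rules) == 19
        levels = [r.modifier_level for r in rules]
        assert levels.count("CC") == 12 and levels.count("MCC") == 7

    def test_pancreatitis_is_mcc_tier(self):
        assert RULES["Acute Pancreatitis"].modifier_level == "MCC"

    def test_death_has_no_qualifying_codes(self):
        assert RULES["Inpatient Death"].qualifying_icd_patterns == ()

    def test_disease_names_unique(self):
        assert len(set(DISEASES)) == 19
        assert set(DISEASE_LEVEL.values()) == {"CC", "MCC"}


class TestEgfrMdrd:
    def test_reference_value(self):
        # independent evaluation of 175 * 2.5^-1.154 * 60^-0.203 * 0.742
        expected = 175.0 * 2.5 ** -1.154 * 60 ** -0.203 * 0.742
        got = egfr_mdrd(2.5, 60, "female", black_race=False)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(19.6, abs=0.05)
        assert got <= 30  # CKD-positive

    def test_sex_and_race_factors_multiplicative(self):
        male = egfr_mdrd(1.0, 50, "male", False)
        assert egfr_mdrd(1.0, 50, "female", False) == pytest.approx(0.742 * male)
        assert egfr_mdrd(1.0, 50, "male", True) == pytest.approx(1.212 * male)

    def test_formula_total_on_positive_reals(self):
        assert egfr_mdrd(1.0, 1.0, "male", False) > 0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            egfr_mdrd(0.0, 60, "female", False)
        with pytest.raises(ValueError):
            egfr_mdrd(1.0, -1, "female", False)


class TestWithinWindow:
    def test_anchor_included_both_directions(self):
        events = [0.0]
        for direction in ("before", "after"):
            assert within_window(events, float, 0.0, 10, direction) == [0.0]

    def test_exact_boundary_included(self):
        assert within_window([-365.0], float, 0.0, 365, "before") == [-365.0]
        assert within_window([365.0], float, 0.0, 365, "after") == [365.0]

    def test_enumeration(self):
        events = [-10.0, -400.0, 1.0]
        assert within_window(events, float, 0.0, 365, "before") == [-10.0]

    def test_bad_args(self):
        with pytest.raises(ValueError):
            within_window([], float, 0.0, 0, "before")
        with pytest.raises(ValueError):
            within_window([], float, 0.0, 1, "sideways")


# Every threshold probed on both sides of its boundary with the rulebook's
# stated strictness.
BOUNDARY_CASES = [
    ("Acidemia", lab(analyte="arterial_pH", value=7.349), True),
    ("Acidemia", lab(analyte="arterial_pH", value=7.35), False),
    ("Hyponatremia", lab(analyte="sodium", value=134.0), True),
    ("Hyponatremia", lab(analyte="sodium", value=134.1), False),
    ("Altered Mental Status", flow(measure="GCS_total", value=8.0), True),
    ("Altered Mental Status", flow(measure="GCS_total", value=9.0), False),
    ("Extremes of BMI", flow(measure="BMI", value=40.1), True),
    ("Extremes of BMI", flow(measure="BMI", value=40.0), False),
    ("Extremes of BMI", flow(measure="BMI", value=19.0), False),
    ("Extremes of BMI", flow(measure="BMI", value=18.9), True),
    ("Acute Pancreatitis", lab(analyte="amylase", value=1000.0), False),
    ("Acute Pancreatitis", lab(analyte="amylase", value=1000.5), True),
    ("Acute Pancreatitis", lab(analyte="lipase", value=450.0), False),
    ("Acute Pancreatitis", lab(analyte="lipase", value=450.5), True),
    ("UTI", culture(specimen="urine", positive=True, colonies=100_000.0), True),
    ("UTI", culture(specimen="urine", positive=True, colonies=99_999.0), False),
    ("Chronic CHF", flow(measure="ejection_fraction", value=30.0, pid="P1", enc=None), True),
    ("Chronic CHF", flow(measure="ejection_fraction", value=30.5, pid="P1", enc=None), False),
    ("Chronic CHF", lab(analyte="BNP", value=900.0), False),
    ("Chronic CHF", lab(analyte="BNP", value=900.5), True),
    ("Myocardial Injury", lab(analyte="troponin", flag="positive"), True),
    ("Myocardial Injury", lab(analyte="troponin", value=5.0, flag="normal"), False),
]


@pytest.mark.parametrize("disease,record,expected", BOUNDARY_CASES,
                         ids=lambda v: str(v)[:48])
def test_threshold_boundaries(disease, record, expected):
    assert detect(disease, [record]) is expected


def test_missing_numeric_value_never_satisfies():
    assert not detect("Acidemia", [lab(analyte="arterial_pH", value=None,
                                       flag="abnormal")])


def test_ckd_egfr_boundary():
    # eGFR exactly 30 is inclusive; creatinine solved from the MDRD closed form
    cut = (175.0 * 55 ** -0.203 * 0.742 / 30.0) ** (1 / 1.154)
    assert detect("Chronic Kidney Disease",
                  [lab(analyte="serum_creatinine", value=cut * 1.001)])
    assert not detect("Chronic Kidney Disease",
                      [lab(analyte="serum_creatinine", value=cut * 0.98)])


def test_bacteremia_requires_two_positive_blood_cultures():
    one = [culture(specimen="blood", positive=True)]
    assert not detect("Bacteremia", one)
    two = one + [culture(specimen="blood", positive=True,
                         when=ADMIT + timedelta(days=1))]
    assert detect("Bacteremia", two)
    assert not detect("Bacteremia", [culture(specimen="blood", positive=True),
                                     culture(specimen="blood", positive=False)])


def test_respiratory_failure_excluded_by_surgery():
    device = flow(measure="airway_device", value="high_flow_nasal_cannula")
    assert detect("Respiratory Failure", [device])
    assert not detect("Respiratory Failure", [device, proc(kind="surgery_case")])
    # a cath-lab stent is not an OR case and does not disqualify
    assert detect("Respiratory Failure", [device, proc(kind="coronary_stent")])


def test_blood_loss_anemia_postop_window():
    t_surg = ADMIT + timedelta(days=1)
    ebl = flow(measure="intraop_blood_loss_mL", value=300.0, when=t_surg)
    hgb_23h = lab(analyte="hemoglobin", value=11.9,
                  when=t_surg + timedelta(hours=23))
    hgb_25h = lab(analyte="hemoglobin", value=11.9,
                  when=t_surg + timedelta(hours=25))
    assert detect("Blood Loss Anemia", [ebl, hgb_23h])
    assert not detect("Blood Loss Anemia", [ebl, hgb_25h])
    # EBL below 300 mL never qualifies
    low_ebl = flow(measure="intraop_blood_loss_mL", value=299.0, when=t_surg)
    assert not detect("Blood Loss Anemia", [low_ebl, hgb_23h])


def test_chf_lookback_window():
    old_ef = flow(measure="ejection_fraction", value=25.0, enc=None, pid="P1",
                  when=ADMIT - timedelta(days=400))
    recent_ef = flow(measure="ejection_fraction", value=25.0, enc=None, pid="P1",
                     when=ADMIT - timedelta(days=200))
    assert not detect("Chronic CHF", [old_ef])
    assert detect("Chronic CHF", [recent_ef])


def test_acute_mi_needs_troponin_and_stent():
    trop = lab(analyte="troponin", flag="positive")
    stent = proc(kind="coronary_stent")
    assert not detect("Acute MI", [trop])
    assert not detect("Acute MI", [stent])
    assert detect("Acute MI", [trop, stent])


def test_transplant_branches():
    assert detect("Transplant", [med(drug="tacrolimus", kind="administration")])
    assert not detect("Transplant", [med(drug="tacrolimus", kind="order_active")])
    historic = proc(kind="transplant_surgery", enc=None, pid="P1",
                    when=ADMIT - timedelta(days=2000))
    assert detect("Transplant", [historic])


def test_death_rule_from_admission_flag():
    cohort = single_admission_cohort(died=True)
    calls = evaluate_cohort(build_rulebook(), cohort)
    positive = [c for c in calls if c.detected]
    assert [c.disease_name for c in positive] == ["Inpatient Death"]
    assert len(calls) == 19


def test_empty_cohort_gives_no_calls():
    assert evaluate_cohort(build_rulebook(), Cohort()) == []


def test_order_invariance_under_record_permutation(small_synth):
    cohort, _ = small_synth
    shuffled = Cohort(admissions=list(cohort.admissions),
                      labs=list(cohort.labs), cultures=list(cohort.cultures),
                      flowsheets=list(cohort.flowsheets),
                      medications=list(cohort.medications),
                      procedures=list(cohort.procedures))
    rng = random.Random(4)
    for table in ("labs", "cultures", "flowsheets", "medications", "procedures"):
        rng.shuffle(shuffled.records(table))
    shuffled.reindex()
    rulebook = build_rulebook()
    assert evaluate_cohort(rulebook, cohort) == evaluate_cohort(rulebook, shuffled)


def test_monotonicity_of_existential_rules():
    base = [lab(analyte="sodium", value=140.0)]
    assert not detect("Hyponatremia", base)
    assert detect("Hyponatremia", base + [lab(analyte="sodium", value=130.0)])
    # Respiratory Failure is the one anti-monotone rule: adding a surgery
    # record flips it true -> false, and removing it restores detection
    device = flow(measure="airway_device", value="endotracheal_tube")
    assert detect("Respiratory Failure", [device])
    assert not detect("Respiratory Failure", [device, proc(kind="surgery_case")])


def test_matches_naive_evaluator_on_synthetic_cohort(small_synth):
    cohort, _ = small_synth
    calls = evaluate_cohort(build_rulebook(), cohort)
    expected = naive_evaluate(cohort)
    for call in calls:
        assert call.detected == expected[(call.encounter_id, call.disease_name)]
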