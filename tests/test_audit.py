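"""ICD matching, DRG catalogue parsing, omission flagging, upgrade logic."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_admission, single_admission_cohort
from drgaudit.audit import (AuditFinding, ICDPattern, ModifierLevel,
                            UpgradeType, build_catalogue, classify_drg,
                            evaluate_upgrade, flag_missing_icd,
                            load_drg_catalogue, match_icd, strip_family)
from drgaudit.phenotypes import build_rulebook, evaluate_rule
from reference_impl import naive_upgrade_target

RULES = {r.disease_name: r for r in build_rulebook()}


class TestMatchIcd:
    @pytest.mark.parametrize("pattern,code,expected", [
        ("I50.*", "I50.9", True),
        ("I50.*", "I50", True),        # wildcard matches its own root
        ("I50.*", "I509", False),      # sibling root, not a dotted child
        ("I50.*", "I51.0", False),
        ("E87.1", "E87.1", True),
        ("E87.1", "E87.11", False),    # literal is exact
        ("K85.*", "K85", True),
        ("K85.*", "K851", False),
        ("K85.*", "K85.90", True),
        ("T86.*", "t86.12 ", True),    # normalization: case and whitespace
    ])
    def test_semantics(self, pattern, code, expected):
        assert match_icd(pattern, code) is expected

    def test_children_only_mode_excludes_root(self):
        assert not match_icd("I50.*", "I50", children_only=True)
        assert match_icd("I50.*", "I50.9", children_only=True)

    def test_malformed_pattern_rejected_at_construction(self):
        with pytest.raises(ValueError):
            ICDPattern("I5*.9")
        with pytest.raises(ValueError):
            ICDPattern("")


class TestFlagMissing:
    def _finding(self, disease, detected_records, codes):
        cohort = single_admission_cohort(detected_records, codes=codes)
        adm = cohort.admissions[0]
        call = evaluate_rule(RULES[disease], adm, cohort)
        return flag_missing_icd(call, adm, RULES[disease])

    def test_detected_with_qualifying_code_not_missing(self):
        from conftest import lab
        f = self._finding("Hyponatremia", [lab(analyte="sodium", value=130.0)],
                          ["E87.1"])
        assert f.detected and f.icd_present and not f.missing_icd

    def test_detected_with_no_codes_is_missing(self):
        from conftest import lab
        f = self._finding("Hyponatremia", [lab(analyte="sodium", value=130.0)], [])
        assert f.detected and not f.icd_present and f.missing_icd

    def test_coded_but_not_detected_counts_as_not_sensitive(self):
        f = self._finding("Acute Pancreatitis", [], ["K85.90"])
        assert not f.detected and f.icd_present and not f.missing_icd

    def test_death_never_flagged_missing(self):
        cohort = single_admission_cohort(died=True, codes=[])
        adm = cohort.admissions[0]
        rule = RULES["Inpatient Death"]
        call = evaluate_rule(rule, adm, cohort)
        f = flag_missing_icd(call, adm, rule)
        assert f.detected and not f.missing_icd

    def test_mismatched_encounter_rejected(self):
        cohort = single_admission_cohort()
        call = evaluate_rule(RULES["Hyponatremia"], cohort.admissions[0], cohort)
        other = make_admission(enc="E2")
        with pytest.raises(ValueError):
            flag_missing_icd(call, other, RULES["Hyponatremia"])


class TestDrgParsing:
    @pytest.mark.parametrize("description,level", [
        ("PLEURAL EFFUSION WITH MCC", ModifierLevel.MCC),
        ("PLEURAL EFFUSION WITH CC", ModifierLevel.CC),
        ("PLEURAL EFFUSION WITHOUT CC/MCC", ModifierLevel.BASE),
        ("CRANIOTOMY WITHOUT MCC", ModifierLevel.BASE),
        ("pleural effusion with mcc", ModifierLevel.MCC),  # case-insensitive
        ("HEART TRANSPLANT", ModifierLevel.SINGLET),
    ])
    def test_classify(self, description, level):
        assert classify_drg(description) is level

    @pytest.mark.parametrize("description,family", [
        ("PLEURAL EFFUSION WITH CC", "PLEURAL EFFUSION"),
        ("PLEURAL EFFUSION WITH MCC", "PLEURAL EFFUSION"),
        ("PLEURAL EFFUSION WITHOUT CC/MCC", "PLEURAL EFFUSION"),
        ("PLEURAL EFFUSION", "PLEURAL EFFUSION"),  # idempotent
        ("X WITH CC/MCC", "X"),                    # doublet arm
        ("X WITHOUT CC", "X"),
    ])
    def test_strip_family(self, description, family):
        assert strip_family(description) == family
        assert strip_family(strip_family(description)) == family

    def test_three_arm_family(self):
        frame = pd.DataFrame({
            "drg_code": ["186", "187", "188"],
            "description": ["PLEURAL EFFUSION WITH MCC",
                            "PLEURAL EFFUSION WITH CC",
                            "PLEURAL EFFUSION WITHOUT CC/MCC"],
            "rwf": [1.4378, 1.0021, 0.8255]})
        cat = build_catalogue(frame)
        assert len(cat) == 3
        assert set(cat.by_family) == {"PLEURAL EFFUSION"}
        assert {e.level for e in cat.entries} == {
            ModifierLevel.MCC, ModifierLevel.CC, ModifierLevel.BASE}

    def test_lone_description_is_singlet_with_family_pass(self):
        frame = pd.DataFrame({"drg_code": ["001"],
                              "description": ["HEART TRANSPLANT"], "rwf": [26.3]})
        cat = build_catalogue(frame)
        assert cat.entries[0].level is ModifierLevel.SINGLET

    def test_suffixless_with_leveled_siblings_becomes_base(self):
        frame = pd.DataFrame({
            "drg_code": ["10", "11"],
            "description": ["CELLULITIS WITH MCC", "CELLULITIS"],
            "rwf": [1.2, 0.6]})
        cat = build_catalogue(frame)
        assert cat.by_code["11"].level is ModifierLevel.BASE

    def test_family_suffix_consistency(self, mini_catalogue):
        # entries sharing a family differ only in the recognized suffix
        for family, entries in mini_catalogue.by_family.items():
            for e in entries:
                assert strip_family(e.description) == family

    def test_empty_and_bad_catalogues(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("drg_code,description,rwf\n")
        assert len(load_drg_catalogue(empty)) == 0
        dup = pd.DataFrame({"drg_code": ["1", "1"],
                            "description": ["A WITH CC", "A WITH MCC"],
                            "rwf": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            build_catalogue(dup)
        no_rwf = pd.DataFrame({"drg_code": ["1"], "description": ["A WITH CC"],
                               "rwf": [float("nan")]})
        with pytest.raises(ValueError, match="rwf"):
            build_catalogue(no_rwf)


def _finding(enc, disease, level, detected=True):
    return AuditFinding(enc, disease, level, detected, False, detected)


class TestEvaluateUpgrade:
    def test_cc_billed_mcc_required(self, mini_catalogue):
        billed = mini_catalogue.by_code["101"]  # WITH CC arm
        flag = evaluate_upgrade(
            [_finding("E1", "Acute Pancreatitis", "MCC")], billed, mini_catalogue)
        assert flag.upgrade_type is UpgradeType.CC_TO_MCC
        assert flag.target_drg.drg_code == "100"
        assert flag.delta_rwf == pytest.approx(
            flag.target_drg.rwf - billed.rwf)

    def test_billed_already_sufficient(self, mini_catalogue):
        billed = mini_catalogue.by_code["100"]  # WITH MCC arm
        flag = evaluate_upgrade(
            [_finding("E1", "Hyponatremia", "CC")], billed, mini_catalogue)
        assert flag.upgrade_type is UpgradeType.NONE
        assert flag.target_drg is None and flag.delta_rwf == 0.0

    def test_highest_level_wins_single_flag(self, mini_catalogue):
        billed = mini_catalogue.by_code["102"]  # base arm
        findings = [_finding("E1", "Hyponatremia", "CC"),
                    _finding("E1", "Acute Pancreatitis", "MCC")]
        flag = evaluate_upgrade(findings, billed, mini_catalogue)
        assert flag.upgrade_type is UpgradeType.BASE_TO_MCC
        assert sorted(flag.driving_diseases) == ["Acute Pancreatitis",
                                                 "Hyponatremia"]

    def test_singlet_never_modified(self, mini_catalogue):
        billed = mini_catalogue.by_code["001"]
        assert billed.level is ModifierLevel.SINGLET
        flag = evaluate_upgrade(
            [_finding("E1", "Acute Pancreatitis", "MCC")], billed, mini_catalogue)
        assert flag.upgrade_type is UpgradeType.NONE

    def test_no_detected_disease_no_upgrade(self, mini_catalogue):
        billed = mini_catalogue.by_code["102"]
        flag = evaluate_upgrade(
            [_finding("E1", "Hyponatremia", "CC", detected=False)],
            billed, mini_catalogue)
        assert flag.upgrade_type is UpgradeType.NONE

    def test_family_missing_required_level_falls_back(self):
        frame = pd.DataFrame({
            "drg_code": ["20", "21"],
            "description": ["GI HEMORRHAGE WITHOUT CC/MCC",
                            "GI HEMORRHAGE WITH CC"],
            "rwf": [0.7, 1.0]})
        cat = build_catalogue(frame)
        flag = evaluate_upgrade(
            [_finding("E1", "Acute Pancreatitis", "MCC")],
            cat.by_code["20"], cat)
        # MCC arm absent: propose the CC arm, the highest the family offers
        assert flag.upgrade_type is UpgradeType.BASE_TO_CC
        assert flag.target_drg.drg_code == "21"

    def test_family_with_nothing_above_billed(self):
        frame = pd.DataFrame({
            "drg_code": ["30"], "description": ["CELLULITIS WITH CC"],
            "rwf": [1.0]})
        cat = build_catalogue(frame)
        flag = evaluate_upgrade(
            [_finding("E1", "Acute Pancreatitis", "MCC")], cat.by_code["30"], cat)
        assert flag.upgrade_type is UpgradeType.NONE

    def test_doublet_cc_mcc_arm(self):
        frame = pd.DataFrame({
            "drg_code": ["40", "41"],
            "description": ["DIABETES WITHOUT CC/MCC", "DIABETES WITH CC/MCC"],
            "rwf": [0.6, 1.0]})
        cat = build_catalogue(frame)
        # base billed, MCC required: the CC/MCC arm serves as the MCC target
        flag = evaluate_upgrade(
            [_finding("E1", "Acute Pancreatitis", "MCC")], cat.by_code["40"], cat)
        assert flag.upgrade_type is UpgradeType.BASE_TO_MCC
        assert flag.target_drg.drg_code == "41"
        # CC/MCC billed satisfies CC; MCC requirement has nothing above it
        flag2 = evaluate_upgrade(
            [_finding("E1", "Acute Pancreatitis", "MCC")], cat.by_code["41"], cat)
        assert flag2.upgrade_type is UpgradeType.NONE

    def test_never_downgrades_delta_nonnegative(self, mini_catalogue):
        rng = np.random.default_rng(0)
        levels = ["CC", "MCC"]
        for _ in range(200):
            billed = mini_catalogue.entries[
                int(rng.integers(len(mini_catalogue.entries)))]
            findings = [_finding("E1", f"D{i}", levels[int(rng.integers(2))],
                                 detected=bool(rng.integers(2)))
                        for i in range(int(rng.integers(0, 4)))]
            flag = evaluate_upgrade(findings, billed, mini_catalogue)
            assert flag.delta_rwf >= 0.0
            if flag.upgrade_type is not UpgradeType.NONE:
                assert flag.target_drg.family == billed.family
                assert flag.target_drg.target_rank > billed.billed_rank

    def test_matches_brute_force_target_search(self, mini_catalogue):
        for billed in mini_catalogue.entries:
            for required in (1, 2):
                flag = evaluate_upgrade(
                    [_finding("E1", "X", "MCC" if required == 2 else "CC")],
                    billed, mini_catalogue)
                expected = naive_upgrade_target(billed, required,
                                                mini_catalogue.entries)
                got = flag.target_drg.drg_code if flag.target_drg else None
                want = expected.drg_code if expected else None
                assert got == want
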