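"""ICD/DRG coding audit.

Three concerns live here:

* ICD wildcard matching — qualifying-code lists use either literal ICD-10
  codes ("E87.1") or prefix families ("I50.*"); a family pattern matches its
  root and any child under the root's dot hierarchy, never a sibling root.
* DRG catalogue parsing — CMS DRG descriptions encode the severity tier in a
  trailing phrase ("... WITH MCC", "... WITH CC", "... WITHOUT CC/MCC").
  Stripping those phrases groups sibling DRGs into a family; a description
  with no tier phrase and no leveled siblings is a "Singlet" whose severity
  cannot be modified.
* Upgrade evaluation — if the severity tier justified by the detected
  phenotypes exceeds the billed DRG's tier, the admission gets a single
  upgrade flag (the highest justified tier wins, eliminating redundancy)
  pointing at the same-family DRG at the required tier.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import AdmissionRecord, normalize_icd
from .phenotypes import PhenotypeCall, PhenotypeRule

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ICD pattern matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICDPattern:
    """A literal ICD-10 code or a trailing-wildcard family pattern."""

    pattern: str

    def __post_init__(self):
        p = self.pattern.strip().upper()
        if not p:
            raise ValueError("empty ICD pattern")
        stem = p[:-2] if p.endswith(".*") else p[:-1] if p.endswith("*") else p
        if "*" in stem:
            raise ValueError(f"malformed ICD pattern {self.pattern!r}: "
                             "wildcard only allowed at the end")
        object.__setattr__(self, "pattern", p)

    @property
    def is_wildcard(self) -> bool:
        return self.pattern.endswith("*")

    @property
    def root(self) -> str:
        if self.pattern.endswith(".*"):
            return self.pattern[:-2]
        if self.pattern.endswith("*"):
            return self.pattern[:-1].rstrip(".")
        return self.pattern

    def matches(self, code: str, children_only: bool = False) -> bool:
        code = normalize_icd(code)
        if not self.is_wildcard:
            return code == self.pattern
        if code == self.root:
            return not children_only
        return code.startswith(self.root + ".")


def match_icd(pattern: Union[str, ICDPattern], code: str,
              children_only: bool = False) -> bool:
    """True if the billed code satisfies the pattern.

    By default a family pattern "X.*" matches the bare root "X" as well as any
    "X.y" child (the audit asks whether any clinically relevant code exists);
    pass ``children_only=True`` for the stricter semantics.
    """
    if not isinstance(pattern, ICDPattern):
        pattern = ICDPattern(pattern)
    return pattern.matches(code, children_only=children_only)


# ---------------------------------------------------------------------------
# Omission flagging
# ---------------------------------------------------------------------------

@dataclass
class AuditFinding:
    encounter_id: str
    disease_name: str
    modifier_level: str  # CC | MCC
    detected: bool
    icd_present: bool
    missing_icd: bool
    drg_inadequate: bool = False


def flag_missing_icd(call: PhenotypeCall, admission: AdmissionRecord,
                     rule: PhenotypeRule) -> AuditFinding:
    """Flag an admission whose clinical evidence lacks any qualifying ICD code.

    Diseases with no qualifying-code list (inpatient death) are never flagged
    as missing; admissions with no billed codes at all are still audited.
    """
    if call.encounter_id != admission.encounter_id:
        raise ValueError("call and admission refer to different encounters")
    patterns = [ICDPattern(p) for p in rule.qualifying_icd_patterns]
    codes = [normalize_icd(c) for c in admission.billed_icd_codes]
    icd_present = any(pat.matches(c) for pat in patterns for c in codes)
    missing = call.detected and not icd_present and bool(patterns)
    return AuditFinding(call.encounter_id, rule.disease_name,
                        rule.modifier_level, call.detected, icd_present, missing)


def findings_to_frame(findings: Sequence[AuditFinding]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in findings])


# ---------------------------------------------------------------------------
# DRG catalogue
# ---------------------------------------------------------------------------

class ModifierLevel(enum.Enum):
    BASE = "BASE"
    CC = "CC"
    MCC = "MCC"
    SINGLET = "SINGLET"


LEVEL_RANK = {ModifierLevel.BASE: 0, ModifierLevel.CC: 1, ModifierLevel.MCC: 2}
RANK_NAME = {0: "base", 1: "CC", 2: "MCC"}

# recognized trailing tier phrases, checked longest-first
_SUFFIXES = [
    (" WITHOUT CC/MCC", ModifierLevel.BASE, 0, 0),
    (" WITHOUT MCC", ModifierLevel.BASE, 0, 0),
    (" WITHOUT CC", ModifierLevel.BASE, 0, 0),
    # doublet upper arm: satisfies CC when billed, serves as the MCC target
    (" WITH CC/MCC", ModifierLevel.MCC, 1, 2),
    (" WITH MCC", ModifierLevel.MCC, 2, 2),
    (" WITH CC", ModifierLevel.CC, 1, 1),
]


def _parse_description(description: str):
    """Return (family, level, billed_rank, target_rank); rank fields are None
    when no tier phrase is recognized (provisional Singlet)."""
    desc = " ".join(description.upper().split()).rstrip(" ,.")
    for suffix, level, billed, target in _SUFFIXES:
        if desc.endswith(suffix):
            return desc[: -len(suffix)].rstrip(" ,."), level, billed, target
    return desc, ModifierLevel.SINGLET, None, None


def classify_drg(description: str) -> ModifierLevel:
    """Severity tier from the trailing phrase of a DRG description.

    A description with no recognized phrase is provisionally SINGLET; the
    catalogue-level family pass (:func:`load_drg_catalogue`) promotes it to
    BASE when leveled siblings exist.
    """
    if not description.strip():
        raise ValueError("empty DRG description")
    return _parse_description(description)[1]


def strip_family(description: str) -> str:
    """Description with the recognized tier phrase removed (idempotent)."""
    return _parse_description(description)[0]


@dataclass
class DRGCatalogueEntry:
    drg_code: str
    description: str
    level: ModifierLevel
    family: str
    rwf: float
    billed_rank: Optional[int]  # None for SINGLET
    target_rank: Optional[int]


@dataclass
class DRGCatalogue:
    entries: list[DRGCatalogueEntry] = field(default_factory=list)

    def __post_init__(self):
        self.by_code = {e.drg_code: e for e in self.entries}
        self.by_family: dict[str, list[DRGCatalogueEntry]] = {}
        for e in self.entries:
            self.by_family.setdefault(e.family, []).append(e)

    def __len__(self):
        return len(self.entries)


def build_catalogue(frame: pd.DataFrame) -> DRGCatalogue:
    """Catalogue from a frame with columns drg_code, description, rwf."""
    entries = []
    seen = set()
    for _, row in frame.iterrows():
        code = str(row["drg_code"]).strip()
        if code in seen:
            raise ValueError(f"duplicate drg_code {code!r} in catalogue")
        seen.add(code)
        rwf = row["rwf"]
        if pd.isna(rwf) or str(rwf).strip() == "":
            raise ValueError(f"missing rwf for DRG {code}")
        family, level, billed, target = _parse_description(str(row["description"]))
        entries.append(DRGCatalogueEntry(code, str(row["description"]).strip(),
                                         level, family, float(rwf), billed, target))
    # family pass: a suffix-less description with leveled siblings is the BASE
    # arm; with no siblings it stays a true Singlet
    families: dict[str, list[DRGCatalogueEntry]] = {}
    for e in entries:
        families.setdefault(e.family, []).append(e)
    for fam_entries in families.values():
        has_leveled = any(e.level is not ModifierLevel.SINGLET for e in fam_entries)
        for e in fam_entries:
            if e.level is ModifierLevel.SINGLET and has_leveled:
                e.level = ModifierLevel.BASE
                e.billed_rank = 0
                e.target_rank = 0
    return DRGCatalogue(entries)


def load_drg_catalogue(path: Union[str, Path]) -> DRGCatalogue:
    """Load a CMS-style catalogue CSV (drg_code, description, rwf)."""
    frame = pd.read_csv(Path(path), dtype={"drg_code": str})
    missing = {"drg_code", "description", "rwf"} - set(frame.columns)
    if missing:
        raise ValueError(f"catalogue is missing column(s) {sorted(missing)}")
    return build_catalogue(frame)


# ---------------------------------------------------------------------------
# Upgrade evaluation
# ---------------------------------------------------------------------------

class UpgradeType(enum.Enum):
    NONE = "none"
    BASE_TO_CC = "base_to_CC"
    BASE_TO_MCC = "base_to_MCC"
    CC_TO_MCC = "CC_to_MCC"


def upgrade_type_for(billed_rank: int, target_rank: int) -> UpgradeType:
    return {
        (0, 1): UpgradeType.BASE_TO_CC,
        (0, 2): UpgradeType.BASE_TO_MCC,
        (1, 2): UpgradeType.CC_TO_MCC,
    }[(billed_rank, target_rank)]


@dataclass
class UpgradeFlag:
    encounter_id: str
    upgrade_type: UpgradeType
    billed_drg: Optional[DRGCatalogueEntry]
    target_drg: Optional[DRGCatalogueEntry] = None
    delta_rwf: float = 0.0
    driving_diseases: list[str] = field(default_factory=list)


def required_level_rank(findings: Sequence[AuditFinding]) -> Optional[int]:
    """Highest severity rank among detected diseases (CC=1, MCC=2), or None."""
    ranks = [2 if f.modifier_level == "MCC" else 1
             for f in findings if f.detected]
    return max(ranks) if ranks else None


def evaluate_upgrade(findings: Sequence[AuditFinding],
                     billed: DRGCatalogueEntry,
                     catalogue: DRGCatalogue) -> UpgradeFlag:
    """At most one upgrade flag per admission.

    The required tier is the maximum over all detected diseases; a Singlet
    billed DRG is never modified; the proposed DRG stays within the billed
    family, falling back to the highest tier the family offers above the
    billed tier when the exact required tier is absent.
    """
    encs = {f.encounter_id for f in findings}
    if len(encs) > 1:
        raise ValueError(f"findings span multiple encounters: {sorted(encs)}")
    enc = next(iter(encs)) if encs else ""
    none_flag = UpgradeFlag(enc, UpgradeType.NONE, billed)

    if billed.level is ModifierLevel.SINGLET or billed.billed_rank is None:
        return none_flag
    required = required_level_rank(findings)
    if required is None or required <= billed.billed_rank:
        return none_flag

    candidates = [e for e in catalogue.by_family.get(billed.family, [])
                  if e.target_rank is not None and e.target_rank > billed.billed_rank
                  and e.drg_code != billed.drg_code]  # a DRG cannot propose itself
    if not candidates:
        return none_flag
    exact = [e for e in candidates if e.target_rank == required]
    if exact:
        target = min(exact, key=lambda e: e.drg_code)
    else:
        best = max(e.target_rank for e in candidates)
        target = min((e for e in candidates if e.target_rank == best),
                     key=lambda e: e.drg_code)

    delta = max(target.rwf - billed.rwf, 0.0)
    driving = [f.disease_name for f in findings if f.detected
               and (2 if f.modifier_level == "MCC" else 1) > billed.billed_rank]
    return UpgradeFlag(enc, upgrade_type_for(billed.billed_rank, target.target_rank),
                       billed, target, delta, driving)
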