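"""Cohort-level audit statistics.

Incidence rates with exact (Clopper-Pearson) binomial confidence intervals,
standardized mean differences for covariate balance between the
accurately-coded and unbilled groups, chi-square reference-group comparisons,
the payor ICD-limit census, and the per-disease audit summary table.

SMD banding convention: small 0-0.4, medium 0.4-0.6, large 0.6-1.0.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .audit import AuditFinding, UpgradeFlag, UpgradeType
from .model import Cohort
from .revenue import PayorClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IncidenceEstimate:
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def incidence_with_ci(k: int, n: int, level: float = 0.95,
                      method: str = "beta") -> IncidenceEstimate:
    """Binomial incidence with an exact Clopper-Pearson interval.

    ``method`` is passed to statsmodels (``"beta"`` = Clopper-Pearson,
    ``"wilson"`` available behind the flag).
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("numerator must be in [0, n]")
    low, high = proportion_confint(k, n, alpha=1 - level, method=method)
    return IncidenceEstimate(k, n, k / n, float(low), float(high), level)


def smd_binary(k1: int, n1: int, k2: int, n2: int) -> float:
    """Standardized mean difference between two binomial proportions:
    |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0.0:
        return 0.0
    return abs(p1 - p2) / np.sqrt(pooled)


def smd_multicategory(counts: pd.DataFrame) -> float:
    """Mahalanobis-type SMD over a categories x 2-groups count table.

    Uses the first K-1 category-proportion components with the pooled
    multinomial covariance; reduces to :func:`smd_binary` for 2 categories.
    Categories empty in both groups are dropped.
    """
    if counts.shape[1] != 2:
        raise ValueError("counts must have exactly two group columns")
    counts = counts.loc[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2:
        raise ValueError("need at least two non-empty categories")
    n1, n2 = counts.iloc[:, 0].sum(), counts.iloc[:, 1].sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    p1 = (counts.iloc[:, 0] / n1).to_numpy()[:-1]
    p2 = (counts.iloc[:, 1] / n2).to_numpy()[:-1]

    def cov(p):
        return np.diag(p) - np.outer(p, p)

    s = (cov(p1) + cov(p2)) / 2.0
    d = p1 - p2
    stat = float(d @ np.linalg.pinv(s) @ d)
    return float(np.sqrt(max(stat, 0.0)))


def reference_group_test(table: Sequence[Sequence[int]],
                         method: str = "chi2") -> float:
    """Two-sided p-value comparing one category against the reference.

    ``table`` is the 2x2 subtable (rows: category, reference; columns: the
    two coding-accuracy groups). Pearson chi-square without continuity
    correction by default; ``method="fisher"`` for small tables. A zero
    margin makes the comparison degenerate and returns p = 1 with a warning.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p-value set to 1",
                      stacklevel=2)
        return 1.0
    if method == "fisher":
        return float(sps.fisher_exact(arr)[1])
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(p) if stat > 0 else 1.0


def icd_limit_census(cohort: Cohort,
                     flags_by_encounter: Mapping[str, UpgradeFlag],
                     payor_of: Mapping[str, PayorClass],
                     limit: int = 25,
                     payor_filter: frozenset = frozenset({PayorClass.MEDICARE}),
                     ) -> tuple[int, int]:
    """Admissions whose billed code list hits the payor's ICD cap.

    Returns (count at/over the cap, subset also eligible for a DRG upgrade).
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    at_limit = 0
    upgradeable = 0
    for adm in cohort.admissions:
        if payor_of.get(adm.encounter_id) not in payor_filter:
            continue
        if len(adm.billed_icd_codes) >= limit:
            at_limit += 1
            flag = flags_by_encounter.get(adm.encounter_id)
            if flag is not None and flag.upgrade_type is not UpgradeType.NONE:
                upgradeable += 1
    return at_limit, upgradeable


# ---------------------------------------------------------------------------
# Per-disease audit summary (four-count table)
# ---------------------------------------------------------------------------

def build_audit_table(findings: Iterable[AuditFinding],
                      flags_by_encounter: Mapping[str, UpgradeFlag],
                      disease_order: Optional[Sequence[str]] = None,
                      ) -> pd.DataFrame:
    """Per-disease summary with four counts and percentages.

    Columns: admissions meeting the clinical criteria; of those, the count
    missing any qualifying ICD code and the count whose DRG modifier was
    inadequate (this disease among the upgrade's driving diseases); and the
    count carrying a qualifying code without meeting the criteria (algorithm
    not sensitive), as a percentage of all code-bearing admissions. A Total
    row sums the columns (admissions can appear in several rows).
    """
    per: dict[str, dict[str, int]] = {}
    for f in findings:
        row = per.setdefault(f.disease_name, {
            "detected": 0, "missing_icd": 0, "drg_inadequate": 0,
            "coded": 0, "not_sensitive": 0})
        if f.detected:
            row["detected"] += 1
        if f.missing_icd:
            row["missing_icd"] += 1
        if f.icd_present:
            row["coded"] += 1
            if not f.detected:
                row["not_sensitive"] += 1
        if f.detected:
            flag = flags_by_encounter.get(f.encounter_id)
            if (flag is not None and flag.upgrade_type is not UpgradeType.NONE
                    and f.disease_name in flag.driving_diseases):
                row["drg_inadequate"] += 1

    order = list(disease_order) if disease_order else sorted(per)
    rows = []
    totals = {k: 0 for k in ("detected", "missing_icd", "drg_inadequate",
                             "coded", "not_sensitive")}
    for disease in order:
        row = per.get(disease, dict.fromkeys(totals, 0))
        for k in totals:
            totals[k] += row[k]
        rows.append(_audit_row(disease, row))
    rows.append(_audit_row("Total", totals))
    return pd.DataFrame(rows)


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


def _audit_row(name: str, row: Mapping[str, int]) -> dict:
    return {
        "disease": name,
        "detected": row["detected"],
        "missing_icd": row["missing_icd"],
        "missing_icd_pct": _pct(row["missing_icd"], row["detected"]),
        "drg_inadequate": row["drg_inadequate"],
        "drg_inadequate_pct": _pct(row["drg_inadequate"], row["detected"]),
        "not_sensitive": row["not_sensitive"],
        "not_sensitive_pct": _pct(row["not_sensitive"], row["coded"]),
    }


# ---------------------------------------------------------------------------
# Demographic balance (accurate vs unbilled coding)
# ---------------------------------------------------------------------------

AGE_BANDS = (
    ("18-35 (young adult)", 18.0, 36.0),
    ("36-64 (middle age)", 36.0, 65.0),
    ("65-78 (aged)", 65.0, 79.0),
    ("79+ (old)", 79.0, float("inf")),
)

REFERENCE_CATEGORIES = {
    "race_ethnicity": "Caucasian-Non-Hispanic",
    "payor": PayorClass.PRIVATE.value,
    "age_group": "36-64 (middle age)",
}


def age_band(age_years: float) -> str:
    for name, lo, hi in AGE_BANDS:
        if lo <= age_years < hi:
            return name
    return AGE_BANDS[0][0] if age_years < AGE_BANDS[0][1] else AGE_BANDS[-1][0]


@dataclass
class BalanceResult:
    variable: str
    counts: pd.DataFrame  # categories x {accurate, unbilled}
    smd: float
    p_values: dict[str, float]  # category -> p vs reference ("REF" omitted)


def balance_table(demographics: pd.DataFrame,
                  test_method: str = "chi2") -> list[BalanceResult]:
    """Covariate balance between accurate and unbilled coding groups.

    ``demographics`` needs columns sex, race_ethnicity, payor, age_group and
    a boolean ``unbilled`` marking admissions flagged for any ICD omission.
    """
    results = []
    group = np.where(demographics["unbilled"].to_numpy(), "unbilled", "accurate")
    for variable in ("sex", "race_ethnicity", "payor", "age_group"):
        counts = pd.crosstab(demographics[variable], group)
        counts = counts.reindex(columns=["accurate", "unbilled"], fill_value=0)
        if counts["accurate"].sum() == 0 or counts["unbilled"].sum() == 0:
            # one coding-accuracy group is empty: no balance comparison exists
            logger.warning("balance for %s skipped: one group is empty", variable)
            results.append(BalanceResult(variable, counts, 0.0, {}))
            continue
        if variable == "sex":
            k1 = int(counts["accurate"].get("male", 0))
            k2 = int(counts["unbilled"].get("male", 0))
            n1, n2 = int(counts["accurate"].sum()), int(counts["unbilled"].sum())
            smd = smd_binary(k1, n1, k2, n2)
            p = reference_group_test(
                [[k1, k2], [n1 - k1, n2 - k2]], method=test_method)
            pvals = {"male vs female": p}
        else:
            smd = smd_multicategory(counts)
            ref = REFERENCE_CATEGORIES[variable]
            pvals = {}
            for cat in counts.index:
                if cat == ref or cat not in counts.index:
                    continue
                sub = [[int(counts.loc[cat, "accurate"]),
                        int(counts.loc[cat, "unbilled"])],
                       [int(counts.loc[ref, "accurate"]),
                        int(counts.loc[ref, "unbilled"])]]
                pvals[cat] = reference_group_test(sub, method=test_method)
        results.append(BalanceResult(variable, counts, smd, pvals))
    return results


def balance_to_frame(results: Sequence[BalanceResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for cat in res.counts.index:
            acc = int(res.counts.loc[cat, "accurate"])
            unb = int(res.counts.loc[cat, "unbilled"])
            if res.variable == "sex":
                p = res.p_values.get("male vs female", float("nan"))
                p_str = f"{p:.3g}"
            else:
                ref = REFERENCE_CATEGORIES[res.variable]
                p = res.p_values.get(cat)
                p_str = "REF" if cat == ref else ("" if p is None else f"{p:.3g}")
            rows.append({
                "variable": res.variable,
                "category": str(cat),
                "accurate": acc,
                "accurate_pct": _pct(acc, int(res.counts["accurate"].sum())),
                "unbilled": unb,
                "unbilled_pct": _pct(unb, int(res.counts["unbilled"].sum())),
                "smd": round(res.smd, 3),
                "p_value": p_str,
            })
    return pd.DataFrame(rows)
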