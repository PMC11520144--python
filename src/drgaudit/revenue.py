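"""Payor consolidation and lost-revenue valuation.

Payors collapse to three classes (Medicare, Medi-Cal, Private) and each class
carries an estimated dollar value per relative-weighting-factor (RWF) point:
$20,000 private, $10,000 Medicare, $7,500 Medi-Cal (2019 estimates, shipped as
defaults and overridable by config). The estimated lost revenue for a flagged
admission is its delta RWF (proposed minus billed DRG weight) times the rate.

All currency arithmetic uses exact decimal cents with half-up rounding at the
line level; binary floating point never accumulates dollars.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .audit import UpgradeFlag, UpgradeType

CENT = Decimal("0.01")
DOLLAR = Decimal("1")


class PayorClass(enum.Enum):
    MEDI_CAL = "MEDI-CAL"
    MEDICARE = "MEDICARE"
    PRIVATE = "PRIVATE"


DEFAULT_PAYOR_MAP: dict[str, PayorClass] = {
    "medicare": PayorClass.MEDICARE,
    "medicare advantage": PayorClass.MEDICARE,
    "medi-cal": PayorClass.MEDI_CAL,
    "medicaid": PayorClass.MEDI_CAL,
}


def group_payor(raw_financial_class: str,
                mapping: Optional[Mapping[str, PayorClass]] = None) -> PayorClass:
    """Consolidate a raw financial class; anything unmapped is Private."""
    mapping = DEFAULT_PAYOR_MAP if mapping is None else mapping
    return mapping.get(raw_financial_class.strip().lower(), PayorClass.PRIVATE)


@dataclass(frozen=True)
class RateSchedule:
    """Estimated dollars per RWF point, by payor class."""

    dollars_per_rwf: Mapping[PayorClass, Decimal] = field(
        default_factory=lambda: {
            PayorClass.PRIVATE: Decimal(20_000),
            PayorClass.MEDICARE: Decimal(10_000),
            PayorClass.MEDI_CAL: Decimal(7_500),
        })

    def __post_init__(self):
        missing = set(PayorClass) - set(self.dollars_per_rwf)
        if missing:
            raise ValueError(f"rate schedule missing {sorted(p.value for p in missing)}")
        for payor, rate in self.dollars_per_rwf.items():
            if rate <= 0:
                raise ValueError(f"non-positive rate for {payor.value}")

    def __getitem__(self, payor: PayorClass) -> Decimal:
        return self.dollars_per_rwf[payor]

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RateSchedule":
        raw = yaml.safe_load(Path(path).read_text())
        return cls({PayorClass(k): Decimal(str(v))
                    for k, v in raw["dollars_per_rwf"].items()})

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"dollars_per_rwf": {p.value: float(r)
                                 for p, r in self.dollars_per_rwf.items()}}))


def load_payor_map(path: Union[str, Path]) -> dict[str, PayorClass]:
    raw = yaml.safe_load(Path(path).read_text())
    return {k.strip().lower(): PayorClass(v) for k, v in raw["payor_map"].items()}


def value_upgrade(flag: UpgradeFlag, payor: PayorClass,
                  rates: Optional[RateSchedule] = None) -> Decimal:
    """Estimated lost dollars for one flagged admission, to the cent."""
    if flag.upgrade_type is UpgradeType.NONE:
        return Decimal("0.00")
    rates = rates or RateSchedule()
    return (Decimal(str(flag.delta_rwf)) * rates[payor]).quantize(
        CENT, rounding=ROUND_HALF_UP)


@dataclass
class RevenueLine:
    upgrade_type: UpgradeType
    payor: PayorClass
    count: int
    added_points: Decimal
    dollars_per_unit: Decimal
    additional_revenue: Decimal  # == added_points * dollars_per_unit, to the cent


def _make_line(utype: UpgradeType, payor: PayorClass, count: int,
               points: Decimal, rates: RateSchedule) -> RevenueLine:
    rate = rates[payor]
    revenue = (points * rate).quantize(CENT, rounding=ROUND_HALF_UP)
    return RevenueLine(utype, payor, count, points, rate, revenue)


_TYPE_ORDER = [UpgradeType.BASE_TO_CC, UpgradeType.BASE_TO_MCC,
               UpgradeType.CC_TO_MCC]


@dataclass
class RevenueSummary:
    lines: list[RevenueLine]
    subtotals_by_type: dict[UpgradeType, Decimal]  # rounded to the dollar
    grand_total: Decimal  # exact cents

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "upgrade_type": ln.upgrade_type.value,
            "payor": ln.payor.value,
            "count": ln.count,
            "added_points": float(ln.added_points),
            "dollars_per_unit": float(ln.dollars_per_unit),
            "estimated_additional_revenue": float(ln.additional_revenue),
        } for ln in self.lines])


def summarize_revenue(flags_with_payors: Iterable[tuple[UpgradeFlag, PayorClass]],
                      rates: Optional[RateSchedule] = None) -> RevenueSummary:
    """Table of estimated lost revenue per (upgrade type, payor) cell.

    Added points are summed in exact decimal; each cell's revenue is points
    times the payor rate rounded half-up to the cent; the grand total is the
    exact sum of cell revenues; per-type subtotals are rounded to the dollar.
    """
    rates = rates or RateSchedule()
    cells: dict[tuple[UpgradeType, PayorClass], tuple[int, Decimal]] = {}
    for flag, payor in flags_with_payors:
        if flag.upgrade_type is UpgradeType.NONE:
            continue
        count, points = cells.get((flag.upgrade_type, payor), (0, Decimal(0)))
        cells[(flag.upgrade_type, payor)] = (
            count + 1, points + Decimal(str(flag.delta_rwf)))
    lines = [_make_line(ut, payor, *cells[(ut, payor)], rates)
             for ut in _TYPE_ORDER
             for payor in sorted(PayorClass, key=lambda p: p.value)
             if (ut, payor) in cells]
    return _summarize_lines(lines)


def summarize_from_aggregates(
        rows: Iterable[tuple[UpgradeType, PayorClass, int, Union[str, float, Decimal]]],
        rates: Optional[RateSchedule] = None) -> RevenueSummary:
    """Summary from pre-aggregated (type, payor, count, added points) rows,
    e.g. when replaying a published revenue table."""
    rates = rates or RateSchedule()
    lines = [_make_line(ut, payor, count, Decimal(str(points)), rates)
             for ut, payor, count, points in rows]
    return _summarize_lines(lines)


def _summarize_lines(lines: list[RevenueLine]) -> RevenueSummary:
    subtotals = {}
    for ut in _TYPE_ORDER:
        cents = sum((ln.additional_revenue for ln in lines
                     if ln.upgrade_type is ut), Decimal(0))
        subtotals[ut] = cents.quantize(DOLLAR, rounding=ROUND_HALF_UP)
    grand = sum((ln.additional_revenue for ln in lines), Decimal(0)).quantize(CENT)
    return RevenueSummary(lines, subtotals, grand)
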