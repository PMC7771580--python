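"""Product supply: defined period and effective (quality-adjusted) supply.

The supply side of the reach model answers: over what period, and in what
area, how much high-quality product was actually available to consumers?
Total supply comes either from sales/distribution volumes or from
production − exports + imports; it is then multiplied by a quality
adjustment factor (fraction of supplied product meeting specification) and
a post-production losses adjustment factor (fraction surviving transport
and storage) to give the effective supply.
"""

from __future__ import annotations

import calendar
import datetime
import enum
import re
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import InconsistentFlowsError, InvalidPeriodError
from .rounding import GRAMS_PER_KG, GRAMS_PER_MT

_YM_RE = re.compile(r"^(\d{4})-(\d{2})$")


def _parse_ym(value: str) -> tuple[int, int]:
    m = _YM_RE.match(value)
    if not m:
        raise ValueError(f"expected calendar month as 'YYYY-MM', got {value!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {value!r}")
    return year, month


class Period(BaseModel):
    """A whole-calendar-month estimation window.

    The period runs from the first day of ``start`` through the last day of
    ``end``, inclusive. Partial months are not representable: reach is
    defined over a period, and every worked example in the field uses whole
    months, so we refuse to guess a convention for fractional boundaries.
    """

    start: str = Field(description="first month, 'YYYY-MM'")
    end: str = Field(description="last month, 'YYYY-MM' (inclusive)")
    label: str = ""

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_order(self) -> "Period":
        if _parse_ym(self.start) > _parse_ym(self.end):
            raise InvalidPeriodError(
                f"period end {self.end} precedes start {self.start}"
            )
        return self

    @property
    def start_date(self) -> datetime.date:
        y, m = _parse_ym(self.start)
        return datetime.date(y, m, 1)

    @property
    def end_date(self) -> datetime.date:
        y, m = _parse_ym(self.end)
        return datetime.date(y, m, calendar.monthrange(y, m)[1])

    @property
    def n_months(self) -> int:
        y0, m0 = _parse_ym(self.start)
        y1, m1 = _parse_ym(self.end)
        return (y1 - y0) * 12 + (m1 - m0) + 1

    def contains(self, day: datetime.date) -> bool:
        return self.start_date <= day <= self.end_date

    def months(self) -> list[str]:
        """All 'YYYY-MM' labels in the period, in order."""
        y, m = _parse_ym(self.start)
        out = []
        for _ in range(self.n_months):
            out.append(f"{y:04d}-{m:02d}")
            m += 1
            if m == 13:
                y, m = y + 1, 1
        return out


def period_length_days(period: Period) -> int:
    """Inclusive day count of the period, honouring leap years.

    e.g. February 2013 through April 2015 (27 months) is 819 days.
    """
    return (period.end_date - period.start_date).days + 1


def average_month_days() -> float:
    """Average month length, 365/12 rounded to one decimal: 30.4 days.

    This is the conventional constant used when a use-frequency is quoted
    "per month" (e.g. trial consumers who use a product for one month).
    Note it is deliberately *not* reconciled with period-specific averages
    such as 819/27 ≈ 30.33; both conventions coexist in practice and the
    model keeps each where it is used.
    """
    return round(365 / 12, 1)


class SupplyMode(str, enum.Enum):
    sales_distribution = "sales_distribution"
    production_flows = "production_flows"


class SupplyUnit(str, enum.Enum):
    grams = "grams"
    kilograms = "kilograms"
    metric_tons = "metric_tons"
    units = "units"  # unit-count, for durables


_UNIT_TO_GRAMS = {
    SupplyUnit.grams: 1.0,
    SupplyUnit.kilograms: GRAMS_PER_KG,
    SupplyUnit.metric_tons: GRAMS_PER_MT,
}


class SupplyInputs(BaseModel):
    """Total product supply in the defined area over the defined period.

    Two measurement routes:

    * ``sales_distribution`` — the dispatch/sales/distribution volume,
      localized to the area (preferred when available);
    * ``production_flows`` — production − exports + imports.

    ``leakage_fraction`` removes supply that leaves the defined area (or,
    equivalently, excess supply never purchased); contraband entering the
    area is simply entered as imports.
    """

    mode: SupplyMode
    sales_volume: Optional[float] = Field(default=None, ge=0)
    production: Optional[float] = Field(default=None, ge=0)
    imports: Optional[float] = Field(default=None, ge=0)
    exports: Optional[float] = Field(default=None, ge=0)
    leakage_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    unit: SupplyUnit = SupplyUnit.metric_tons

    @model_validator(mode="after")
    def _check_mode_fields(self) -> "SupplyInputs":
        if self.mode is SupplyMode.sales_distribution:
            if self.sales_volume is None:
                raise ValueError("sales_distribution mode requires sales_volume")
            if any(v is not None for v in (self.production, self.imports, self.exports)):
                raise ValueError(
                    "sales_distribution mode must not carry production/imports/exports"
                )
        else:
            if self.production is None:
                raise ValueError("production_flows mode requires production")
            if self.sales_volume is not None:
                raise ValueError("production_flows mode must not carry sales_volume")
        return self

    @property
    def is_count(self) -> bool:
        return self.unit is SupplyUnit.units

    def to_canonical(self, quantity: float) -> float:
        """Convert a quantity in this input's unit to grams (or a count)."""
        if self.is_count:
            return quantity
        return quantity * _UNIT_TO_GRAMS[self.unit]


class AdjustmentFactors(BaseModel):
    """Quality and post-production-loss adjustments, each in [0, 1].

    1.0 means no loss: all supply meets specification (quality) or all
    supply survives to the consumer (losses). The maximum-reach assumption
    when no data exist is both factors = 1.
    """

    quality_factor: float = Field(default=1.0, ge=0.0, le=1.0)
    losses_factor: float = Field(default=1.0, ge=0.0, le=1.0)

    model_config = {"frozen": True}


class EffectiveSupply(BaseModel):
    """Quantity of high-quality product available to consumers.

    ``quantity`` is in grams for mass-based products and a unit count for
    durables (``kind`` distinguishes the two).
    """

    quantity: float = Field(ge=0)
    kind: str = "mass"  # "mass" (grams) or "count" (units)
    period: Optional[Period] = None
    area_label: str = ""

    model_config = {"frozen": True}


def total_supply(inputs: SupplyInputs) -> float:
    """Total supply in canonical units (grams, or a count for durables).

    Sales mode: sales_volume × (1 − leakage). Flows mode:
    (production − exports + imports) × (1 − leakage); negative flow
    balances are rejected rather than clamped, since exports exceeding
    production + imports means the inputs are inconsistent.
    """
    keep = 1.0 - inputs.leakage_fraction
    if inputs.mode is SupplyMode.sales_distribution:
        raw = inputs.sales_volume
    else:
        raw = inputs.production - (inputs.exports or 0.0) + (inputs.imports or 0.0)
        if raw < 0:
            raise InconsistentFlowsError(
                f"exports exceed production + imports (net {raw:g} {inputs.unit.value})"
            )
    return inputs.to_canonical(raw * keep)


def effective_supply(
    total: float,
    factors: AdjustmentFactors,
    *,
    period: Optional[Period] = None,
    area_label: str = "",
    kind: str = "mass",
) -> EffectiveSupply:
    """total × quality_factor × losses_factor, tagged with period and area."""
    if total < 0:
        raise ValueError("total supply must be non-negative")
    return EffectiveSupply(
        quantity=total * factors.quality_factor * factors.losses_factor,
        kind=kind,
        period=period,
        area_label=area_label,
    )
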