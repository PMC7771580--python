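"""Consumer use patterns: how much product one consumer uses in the period.

Fast-moving goods: per-consumer use = amount used per use-day × number of
use-days in the period. The daily amount starts from a measured or
recommended base and is narrowed by multiplicative share factors (e.g. the
share of consumption happening at home, or the share of that consumption
that is the target product) and a unit-conversion divisor (e.g. cooked→dry
mass).

Durable goods: reach per unit is governed by the average number of users
per unit (D) and the number of units one consumer goes through in the
period (turnover, E = period ÷ length of use, floored at one unit).
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .rounding import RoundingPolicy


class Basis(str, enum.Enum):
    """Whether a value was measured directly or taken from a recommendation."""

    measured = "measured"
    recommended = "recommended"


class Multiplier(BaseModel):
    name: str
    value: float = Field(ge=0.0, le=1.0)

    model_config = {"frozen": True}


class FastMovingUseSpec(BaseModel):
    base_daily_amount: float = Field(gt=0, description="grams/person/use-day before adjustment")
    amount_basis: Basis = Basis.measured
    multipliers: list[Multiplier] = Field(default_factory=list)
    conversion_divisor: float = Field(default=1.0, gt=0)
    use_days: float = Field(gt=0, description="use-days in the period")
    frequency_basis: Basis = Basis.measured


class DurableUseSpec(BaseModel):
    """Either a scalar users-per-unit or a distribution over household sizes."""

    users_per_unit: Optional[float] = Field(default=None, gt=0)
    household_distribution: Optional[list[tuple[float, float]]] = Field(
        default=None, description="(weight, users-per-unit) pairs; weights sum to 1"
    )
    length_of_use_days: float = Field(gt=0)
    basis: Basis = Basis.measured

    @model_validator(mode="after")
    def _check_exactly_one(self) -> "DurableUseSpec":
        if (self.users_per_unit is None) == (self.household_distribution is None):
            raise ValueError(
                "give exactly one of users_per_unit or household_distribution"
            )
        if self.household_distribution is not None:
            weights = [w for w, _ in self.household_distribution]
            if any(not 0 <= w <= 1 for w in weights):
                raise ValueError("distribution weights must lie in [0, 1]")
            if not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"distribution weights must sum to 1 (got {sum(weights):g})"
                )
            if any(u <= 0 for _, u in self.household_distribution):
                raise ValueError("users-per-unit values must be positive")
        return self


class PerConsumerUse(BaseModel):
    """Quantity one consumer uses over the period (grams, or units)."""

    quantity: float = Field(gt=0)
    basis_note: str = ""

    model_config = {"frozen": True}


def effective_daily_amount(spec: FastMovingUseSpec, policy: RoundingPolicy) -> float:
    """Adjusted grams used per consumer per use-day.

    base × Π(multipliers) ÷ conversion_divisor. In replication mode the
    result is rounded to 0.1 g, the precision such figures are printed at.
    """
    amount = spec.base_daily_amount
    for m in spec.multipliers:
        amount *= m.value
    amount /= spec.conversion_divisor
    return policy.daily_amount(amount)


def per_consumer_period_use(
    daily: float,
    use_days: float,
    policy: RoundingPolicy,
    *,
    period_days: Optional[float] = None,
    basis_note: str = "",
) -> PerConsumerUse:
    """Mass one consumer uses over the period: daily × use_days.

    Replication mode rounds to the nearest gram. If ``period_days`` is
    given, ``use_days`` may not exceed it (one cannot use a product on more
    days than the period has).
    """
    if daily <= 0:
        raise ValueError("daily amount must be positive")
    if use_days <= 0:
        raise ValueError("use_days must be positive")
    if period_days is not None and use_days > period_days + 1e-9:
        raise ValueError(
            f"use_days ({use_days:g}) exceeds period length ({period_days:g})"
        )
    return PerConsumerUse(
        quantity=policy.period_mass(daily * use_days), basis_note=basis_note
    )


def users_per_unit(spec: DurableUseSpec) -> float:
    """Average number of users per product unit (D).

    Scalar when given directly; otherwise the weighted average over the
    household-size distribution.
    """
    if spec.users_per_unit is not None:
        return spec.users_per_unit
    return sum(w * u for w, u in spec.household_distribution)


def turnover_units(period_days: float, length_of_use_days: float) -> float:
    """Units one consumer goes through in the period (E).

    period ÷ length of use when the product wears out within the period;
    1 when the product outlives the period (each consumer uses a single
    unit). Returned unrounded — it is an intermediate rate.
    """
    if period_days <= 0 or length_of_use_days <= 0:
        raise ValueError("period and length of use must be positive")
    if length_of_use_days >= period_days:
        return 1.0
    return period_days / length_of_use_days
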