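"""Reach estimation: convert supply and use (or coverage) into headcounts.

Three estimation formulas, mirroring the two main routes to reach:

* F1 — coverage route: reach = coverage × target population.
* F2 — durable goods: reach = effective units × users-per-unit ÷ turnover.
* F3 — fast-moving goods: reach = effective supply ÷ per-consumer use.

Every result carries the assumptions ledger that produced it: a model is
only as good as its inputs, and each default, proxy measure and homogeneity
assumption must be reported alongside the headcount it shaped.
"""

from __future__ import annotations

import enum
import math
import warnings
from typing import Optional, Union

from pydantic import BaseModel, Field, model_validator

from .errors import DoubleCountingError, ZeroUseError
from .rounding import RoundingPolicy, FULL_PRECISION
from .supply import EffectiveSupply
from .use import PerConsumerUse


class Formula(str, enum.Enum):
    F1 = "F1"  # coverage × population
    F2 = "F2"  # durable: units × users-per-unit / turnover
    F3 = "F3"  # fast-moving: supply / per-consumer use


class CoverageScope(str, enum.Enum):
    total = "total"
    target_group = "target_group"


class CoverageInput(BaseModel):
    """Directly measured coverage plus the matching population figure.

    ``scope`` says whether both numbers refer to the total population of
    the area or to a specific target group; mixing scopes (e.g. target-group
    coverage × total population) is a category error the type prevents.
    """

    coverage: float = Field(ge=0.0, le=1.0)
    population: float = Field(ge=0)
    scope: CoverageScope = CoverageScope.total

    model_config = {"frozen": True}


class ConsumerSegment(BaseModel):
    """A consumer group with its own share of supply and use intensity.

    e.g. repeat purchasers consuming the product throughout the period vs
    trial purchasers who use it for about a month and stop.
    """

    name: str
    supply_share: float = Field(ge=0.0, le=1.0)
    per_consumer_use: PerConsumerUse

    model_config = {"frozen": True}


class SubgroupSpec(BaseModel):
    """A subpopulation of interest as a fraction of the total population.

    Fractions need not partition the population: women of reproductive age,
    young children and socioeconomic classes overlap freely.
    """

    name: str
    population_fraction: float = Field(ge=0.0, le=1.0)

    model_config = {"frozen": True}


class AssumptionRecord(BaseModel):
    """One explained assumption: which element, which measure, what value."""

    element: str
    measure: str = ""
    basis: str = ""
    value: Union[float, str, None] = None

    model_config = {"frozen": True}


class ReachResult(BaseModel):
    total_reach: int = Field(ge=0)
    segment_reach: dict[str, int] = Field(default_factory=dict)
    subgroup_reach: dict[str, int] = Field(default_factory=dict)
    component_reach: dict[str, int] = Field(
        default_factory=dict,
        description="razor/blade component estimates, when applicable",
    )
    formula_used: Formula
    assumptions_ledger: list[AssumptionRecord] = Field(default_factory=list)
    policy: RoundingPolicy = FULL_PRECISION

    @model_validator(mode="after")
    def _check_consistency(self) -> "ReachResult":
        if self.segment_reach:
            diff = abs(self.total_reach - sum(self.segment_reach.values()))
            if diff > len(self.segment_reach):
                raise ValueError(
                    "total_reach must equal the segment sum within rounding"
                )
        for name, count in self.subgroup_reach.items():
            if count > self.total_reach:
                raise ValueError(f"subgroup {name!r} exceeds total reach")
        return self


def reach_from_coverage(inp: CoverageInput) -> ReachResult:
    """F1: headcount = coverage × population, rounded to whole persons."""
    total = round_headcount(inp.coverage * inp.population)
    ledger = [
        AssumptionRecord(
            element="coverage",
            measure="h1" if inp.scope is CoverageScope.total else "h2",
            basis="measured",
            value=inp.coverage,
        ),
        AssumptionRecord(
            element="population",
            measure="i1" if inp.scope is CoverageScope.total else "i2",
            value=inp.population,
        ),
    ]
    return ReachResult(
        total_reach=total, formula_used=Formula.F1, assumptions_ledger=ledger
    )


def coverage_from_reach(reach: float, population: float) -> float:
    """Reach expressed as a proportion of a population.

    The ratio is returned unclamped; a value above 1 (reach exceeding the
    stated population, i.e. inconsistent inputs) raises a warning so
    triangulation can surface the discrepancy rather than hide it.
    """
    if population <= 0:
        raise ValueError("population must be positive to express coverage")
    ratio = reach / population
    if ratio > 1:
        warnings.warn(
            f"reach ({reach:g}) exceeds population ({population:g}); "
            "coverage ratio > 1 indicates inconsistent inputs",
            stacklevel=2,
        )
    return ratio


def round_headcount(value: float) -> int:
    from .rounding import headcount

    return headcount(value)


def reach_fast_moving(
    supply: EffectiveSupply, use: PerConsumerUse, policy: RoundingPolicy
) -> ReachResult:
    """F3: effective supply ÷ per-consumer period use."""
    if use.quantity <= 0:
        raise ZeroUseError("per-consumer use must be positive")
    total = policy.headcount(supply.quantity / use.quantity)
    return ReachResult(total_reach=total, formula_used=Formula.F3, policy=policy)


def reach_durable(
    units: EffectiveSupply,
    users_per_unit: float,
    turnover: float,
    policy: RoundingPolicy,
) -> ReachResult:
    """F2: effective units × users-per-unit ÷ turnover.

    Turnover (units per consumer over the period) divides: a consumer who
    goes through five units in the period accounts for five of them, so the
    unit count supports fewer distinct people, not more.
    """
    if units.kind != "count":
        raise ValueError("durable reach needs a unit-count supply, not a mass")
    if turnover < 1:
        raise ValueError("turnover must be >= 1 (one unit per consumer minimum)")
    if users_per_unit <= 0:
        raise ZeroUseError("users per unit must be positive")
    total = policy.headcount(units.quantity * users_per_unit / turnover)
    return ReachResult(total_reach=total, formula_used=Formula.F2, policy=policy)


def segmented_reach(
    supply: EffectiveSupply,
    segments: list[ConsumerSegment],
    policy: RoundingPolicy,
) -> ReachResult:
    """Reach summed over consumer segments that split the supply.

    Each segment receives its share of the effective supply (replication
    mode rounds the share to 0.01 metric ton, the printed precision) and is
    divided by that segment's own per-consumer use. The total is the sum of
    segment headcounts: within-segment homogeneity is assumed, and segments
    are assumed disjoint sets of people.
    """
    share_sum = sum(s.supply_share for s in segments)
    if not math.isclose(share_sum, 1.0, abs_tol=1e-9):
        raise ValueError(f"segment supply shares must sum to 1 (got {share_sum:g})")
    seg_counts: dict[str, int] = {}
    ledger: list[AssumptionRecord] = []
    for seg in segments:
        seg_supply = policy.segment_supply(supply.quantity * seg.supply_share)
        seg_counts[seg.name] = policy.headcount(seg_supply / seg.per_consumer_use.quantity)
        ledger.append(
            AssumptionRecord(
                element=f"segment:{seg.name}",
                measure="supply_share",
                basis=seg.per_consumer_use.basis_note,
                value=seg.supply_share,
            )
        )
    return ReachResult(
        total_reach=sum(seg_counts.values()),
        segment_reach=seg_counts,
        formula_used=Formula.F3,
        assumptions_ledger=ledger,
        policy=policy,
    )


def subgroup_reach(
    total: int, subgroups: list[SubgroupSpec], policy: RoundingPolicy
) -> dict[str, int]:
    """Allocate a total headcount to subpopulations by population fraction.

    Assumes use patterns do not differ across subgroups (the allocation is
    proportional); the caller should record that assumption in the ledger.
    Subgroups may overlap, so the counts need not sum to the total.
    """
    if total < 0:
        raise ValueError("total reach must be non-negative")
    return {
        sg.name: policy.headcount(total * sg.population_fraction) for sg in subgroups
    }


def razor_blade_reach(
    razor: Optional[ReachResult], blade: Optional[ReachResult]
) -> ReachResult:
    """Combine durable ("razor") and consumable ("blade") component estimates.

    With both components the combined estimate is the smaller of the two —
    the conservative bound, since a person is only reached by the bundle if
    reached by each part — and both raw component values are reported. With
    one component, that component stands in for the bundle.
    """
    if razor is None and blade is None:
        raise ValueError("razor-and-blade estimate needs at least one component")
    components: dict[str, int] = {}
    ledger: list[AssumptionRecord] = []
    if razor is not None:
        components["razor"] = razor.total_reach
        ledger.extend(razor.assumptions_ledger)
    if blade is not None:
        components["blade"] = blade.total_reach
        ledger.extend(blade.assumptions_ledger)
    if razor is not None and blade is not None:
        total = min(razor.total_reach, blade.total_reach)
        formula = (
            razor.formula_used
            if razor.total_reach <= blade.total_reach
            else blade.formula_used
        )
        ledger.append(
            AssumptionRecord(
                element="razor_blade_combination",
                measure="min(razor, blade)",
                value="conservative bound",
            )
        )
    else:
        only = razor if razor is not None else blade
        total, formula = only.total_reach, only.formula_used
        ledger.append(
            AssumptionRecord(
                element="razor_blade_combination",
                measure="single component",
                value="razor" if razor is not None else "blade",
            )
        )
    policy = (razor or blade).policy
    return ReachResult(
        total_reach=total,
        component_reach=components,
        formula_used=formula,
        assumptions_ledger=ledger,
        policy=policy,
    )


class MonthlyReachSeries:
    """Per-month reach estimates for trend review.

    Monthly values show delivery trends, but the same individual typically
    uses the product in several months, so *summing* monthly headcounts
    double-counts people. Any attempt to total this series raises
    :class:`~reachcalc.errors.DoubleCountingError`; estimate period reach
    from supply aggregated over the whole period instead.
    """

    def __init__(self, results: dict[str, ReachResult]):
        self._results = dict(results)

    @property
    def months(self) -> list[str]:
        return list(self._results)

    def __getitem__(self, month: str) -> ReachResult:
        return self._results[month]

    def __len__(self) -> int:
        return len(self._results)

    def reach_by_month(self) -> dict[str, int]:
        return {m: r.total_reach for m, r in self._results.items()}

    def total(self) -> int:
        raise DoubleCountingError(
            "monthly reach values must not be summed into a period total: "
            "individuals using the product in several months would be "
            "counted once per month. Aggregate supply over the full period "
            "and estimate reach once."
        )

    sum = total  # either spelling raises


def monthly_reach(
    supply_by_month: dict[str, EffectiveSupply],
    use_per_month: PerConsumerUse,
    policy: RoundingPolicy,
) -> MonthlyReachSeries:
    """Fast-moving reach per month, for trend review only (not summable)."""
    return MonthlyReachSeries(
        {
            month: reach_fast_moving(supply, use_per_month, policy)
            for month, supply in supply_by_month.items()
        }
    )
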