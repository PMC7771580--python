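"""End-to-end estimation: a validated ProductConfig in, a ReachResult out.

This is the orchestration layer: it resolves the period, builds effective
supply and per-consumer use from the config, dispatches to the right
formula (coverage, fast-moving, durable, or razor-and-blade), allocates
subgroups, and assembles the assumptions ledger along the way.
"""

from __future__ import annotations

from typing import Optional

from .config import ComponentConfig, ProductConfig, ProductType, SupplyConfig
from .engine import (
    AssumptionRecord,
    CoverageInput,
    ConsumerSegment,
    ReachResult,
    razor_blade_reach,
    reach_durable,
    reach_fast_moving,
    reach_from_coverage,
    segmented_reach,
    subgroup_reach,
)
from .rounding import FULL_PRECISION, RoundingPolicy
from .supply import (
    EffectiveSupply,
    effective_supply,
    period_length_days,
    total_supply,
)
from .use import (
    effective_daily_amount,
    per_consumer_period_use,
    turnover_units,
    users_per_unit,
)


def _effective_supply_from_config(
    config: ProductConfig, sup: SupplyConfig, kind: str
) -> EffectiveSupply:
    return effective_supply(
        total_supply(sup.to_inputs()),
        sup.to_factors(),
        period=config.period,
        area_label=config.area,
        kind=kind,
    )


def _supply_ledger_records(prefix: str, sup: SupplyConfig) -> list[AssumptionRecord]:
    measure = "a1" if sup.mode.value == "sales_distribution" else "a2"
    volume = sup.sales_volume if measure == "a1" else sup.production
    return [
        AssumptionRecord(
            element=f"{prefix}.volume", measure=measure, value=volume
        ),
        AssumptionRecord(
            element=f"{prefix}.quality_factor", measure="b1", value=sup.quality_factor
        ),
        AssumptionRecord(
            element=f"{prefix}.losses_factor", measure="c1", value=sup.losses_factor
        ),
    ]


def _fast_moving(
    config: ProductConfig,
    sup: SupplyConfig,
    use_cfg,
    policy: RoundingPolicy,
    prefix: str = "supply",
) -> ReachResult:
    pdays = period_length_days(config.period)
    supply = _effective_supply_from_config(config, sup, "mass")
    ledger = _supply_ledger_records(prefix, sup)
    ledger.append(
        AssumptionRecord(
            element="use_amount",
            measure="f1" if use_cfg.amount_basis.value == "measured" else "f2",
            basis=use_cfg.amount_basis.value,
            value=use_cfg.base_daily_amount,
        )
    )
    for mult in use_cfg.multipliers:
        ledger.append(
            AssumptionRecord(
                element=f"use_amount.multiplier:{mult.name}", value=mult.value
            )
        )

    if config.segments and prefix == "supply":
        segments = []
        for seg_cfg in config.segments:
            seg_use_cfg = config.segment_use(seg_cfg)
            spec = seg_use_cfg.to_spec(pdays)
            daily = effective_daily_amount(spec, policy)
            use = per_consumer_period_use(
                daily,
                spec.use_days,
                policy,
                period_days=pdays,
                basis_note=f"{spec.amount_basis.value} amount, "
                f"{spec.frequency_basis.value} frequency",
            )
            segments.append(
                ConsumerSegment(
                    name=seg_cfg.name,
                    supply_share=seg_cfg.supply_share,
                    per_consumer_use=use,
                )
            )
            ledger.append(
                AssumptionRecord(
                    element=f"use_frequency:{seg_cfg.name}",
                    measure="g1"
                    if seg_use_cfg.frequency_basis.value == "measured"
                    else "g2",
                    basis=seg_use_cfg.frequency_basis.value,
                    value=spec.use_days,
                )
            )
        result = segmented_reach(supply, segments, policy)
    else:
        spec = use_cfg.to_spec(pdays)
        daily = effective_daily_amount(spec, policy)
        use = per_consumer_period_use(
            daily, spec.use_days, policy, period_days=pdays
        )
        ledger.append(
            AssumptionRecord(
                element="use_frequency",
                measure="g1" if spec.frequency_basis.value == "measured" else "g2",
                basis=spec.frequency_basis.value,
                value=spec.use_days,
            )
        )
        result = reach_fast_moving(supply, use, policy)
    return result.model_copy(
        update={"assumptions_ledger": ledger + result.assumptions_ledger}
    )


def _durable(
    config: ProductConfig,
    sup: SupplyConfig,
    use_cfg,
    policy: RoundingPolicy,
    prefix: str = "supply",
) -> ReachResult:
    pdays = period_length_days(config.period)
    units = _effective_supply_from_config(config, sup, "count")
    spec = use_cfg.to_spec()
    d = users_per_unit(spec)
    e = turnover_units(pdays, spec.length_of_use_days)
    ledger = _supply_ledger_records(prefix, sup)
    ledger.extend(
        [
            AssumptionRecord(element="users_per_unit", measure="d1", value=d),
            AssumptionRecord(
                element="length_of_use",
                measure="e1" if spec.basis.value == "measured" else "e2",
                basis=spec.basis.value,
                value=spec.length_of_use_days,
            ),
        ]
    )
    result = reach_durable(units, d, e, policy)
    return result.model_copy(
        update={"assumptions_ledger": ledger + result.assumptions_ledger}
    )


def _component(
    config: ProductConfig, name: str, comp: ComponentConfig, policy: RoundingPolicy
) -> ReachResult:
    if comp.use.type == "durable":
        return _durable(config, comp.supply, comp.use, policy, prefix=name)
    return _fast_moving(config, comp.supply, comp.use, policy, prefix=name)


def _apply_subgroups(
    config: ProductConfig, result: ReachResult, policy: RoundingPolicy
) -> ReachResult:
    if not config.subgroups:
        return result
    specs = [s.to_engine_spec() for s in config.subgroups]
    counts = subgroup_reach(result.total_reach, specs, policy)
    ledger = result.assumptions_ledger + [
        AssumptionRecord(
            element="subgroup_allocation",
            basis="assumed",
            value="use patterns homogeneous across subgroups",
        )
    ]
    return result.model_copy(
        update={"subgroup_reach": counts, "assumptions_ledger": ledger}
    )


def estimate(
    config: ProductConfig, policy: RoundingPolicy = FULL_PRECISION
) -> ReachResult:
    """Estimate product reach for a validated config.

    Supply-based estimation (F2/F3) is used whenever a supply block is
    present; a config carrying only coverage data uses the coverage route
    (F1). Use :func:`coverage_estimate` and the report bundle for
    triangulating the two routes against each other.
    """
    defaults = config.default_assumptions()
    if config.product_type is ProductType.razor_blade:
        parts: dict[str, Optional[ReachResult]] = {"razor": None, "blade": None}
        for name, comp in config.components.items():
            parts[name] = _component(config, name, comp, policy)
        result = razor_blade_reach(parts["razor"], parts["blade"])
        result = result.model_copy(update={"policy": policy})
    elif config.supply is not None:
        if config.product_type is ProductType.fast_moving:
            result = _fast_moving(config, config.supply, config.use, policy)
        else:
            result = _durable(config, config.supply, config.use, policy)
    else:
        result = coverage_estimate(config)
    result = result.model_copy(
        update={"assumptions_ledger": defaults + result.assumptions_ledger}
    )
    return _apply_subgroups(config, result, policy)


def coverage_estimate(config: ProductConfig) -> ReachResult:
    """The coverage route (F1) alone; needs a coverage block."""
    if config.coverage is None:
        raise ValueError("config has no coverage block")
    cov = config.coverage
    return reach_from_coverage(
        CoverageInput(
            coverage=cov.coverage, population=cov.population, scope=cov.scope
        )
    )
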