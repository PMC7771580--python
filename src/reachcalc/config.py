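"""Config schema, loading/validation and supply-ledger ingestion.

A product config is one YAML (or JSON) document describing everything the
model needs for one product: the period and area, the supply route and
adjustment factors, the consumer-use pattern, and optional consumer
segments, subgroups and coverage figures. Validation reports all problems
at once, and every default the loader applies is recorded as an explained
assumption.
"""

from __future__ import annotations

import datetime
import enum
import math
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .engine import AssumptionRecord, SubgroupSpec
from .errors import ConfigError, LedgerRowError
from .rounding import GRAMS_PER_KG, GRAMS_PER_MT
from .supply import (
    AdjustmentFactors,
    Period,
    SupplyInputs,
    SupplyMode,
    SupplyUnit,
)
from .use import Basis, DurableUseSpec, FastMovingUseSpec, Multiplier


class ProductType(str, enum.Enum):
    fast_moving = "fast_moving"
    durable = "durable"
    razor_blade = "razor_blade"


class SupplyConfig(BaseModel):
    """Supply inputs and adjustment factors as one config mapping."""

    mode: SupplyMode = SupplyMode.sales_distribution
    sales_volume: Optional[float] = Field(default=None, ge=0)
    production: Optional[float] = Field(default=None, ge=0)
    imports: Optional[float] = Field(default=None, ge=0)
    exports: Optional[float] = Field(default=None, ge=0)
    leakage_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    unit: SupplyUnit = SupplyUnit.metric_tons
    quality_factor: float = Field(default=1.0, ge=0.0, le=1.0)
    losses_factor: float = Field(default=1.0, ge=0.0, le=1.0)

    def to_inputs(self) -> SupplyInputs:
        return SupplyInputs(
            mode=self.mode,
            sales_volume=self.sales_volume,
            production=self.production,
            imports=self.imports,
            exports=self.exports,
            leakage_fraction=self.leakage_fraction,
            unit=self.unit,
        )

    def to_factors(self) -> AdjustmentFactors:
        return AdjustmentFactors(
            quality_factor=self.quality_factor, losses_factor=self.losses_factor
        )

    @model_validator(mode="after")
    def _mode_fields(self) -> "SupplyConfig":
        # delegate mode/field coherence to the SupplyInputs validator
        self.to_inputs()
        return self


class FastMovingUseConfig(BaseModel):
    type: Literal["fast_moving"] = "fast_moving"
    base_daily_amount: float = Field(gt=0)
    amount_basis: Basis = Basis.measured
    multipliers: list[Multiplier] = Field(default_factory=list)
    conversion_divisor: float = Field(default=1.0, gt=0)
    use_days: Union[float, Literal["period"]] = "period"
    frequency_basis: Basis = Basis.measured

    @model_validator(mode="after")
    def _check_days(self) -> "FastMovingUseConfig":
        if self.use_days != "period" and float(self.use_days) <= 0:
            raise ValueError("use_days must be positive")
        return self

    def resolve_days(self, period_days: float) -> float:
        """'period' means every day of the period (daily-use staple)."""
        return period_days if self.use_days == "period" else float(self.use_days)

    def to_spec(self, period_days: float) -> FastMovingUseSpec:
        return FastMovingUseSpec(
            base_daily_amount=self.base_daily_amount,
            amount_basis=self.amount_basis,
            multipliers=self.multipliers,
            conversion_divisor=self.conversion_divisor,
            use_days=self.resolve_days(period_days),
            frequency_basis=self.frequency_basis,
        )


class DurableUseConfig(BaseModel):
    type: Literal["durable"] = "durable"
    users_per_unit: Optional[float] = Field(default=None, gt=0)
    household_distribution: Optional[list[tuple[float, float]]] = None
    length_of_use_days: float = Field(gt=0)
    basis: Basis = Basis.measured

    def to_spec(self) -> DurableUseSpec:
        return DurableUseSpec(
            users_per_unit=self.users_per_unit,
            household_distribution=self.household_distribution,
            length_of_use_days=self.length_of_use_days,
            basis=self.basis,
        )


UseConfig = Union[FastMovingUseConfig, DurableUseConfig]


class SegmentConfig(BaseModel):
    """A consumer segment: supply share plus optional use overrides.

    ``use`` is a partial mapping merged over the product's base use config,
    so a segment typically only states what differs (e.g. trial consumers'
    shorter use_days).
    """

    name: str
    supply_share: float = Field(ge=0.0, le=1.0)
    use: Optional[dict] = None


class SubgroupConfig(BaseModel):
    name: str
    population_fraction: float = Field(ge=0.0, le=1.0)

    def to_engine_spec(self) -> SubgroupSpec:
        return SubgroupSpec(
            name=self.name, population_fraction=self.population_fraction
        )


class CoverageConfig(BaseModel):
    coverage: float = Field(ge=0.0, le=1.0)
    population: float = Field(ge=0)
    scope: Literal["total", "target_group"] = "total"


class ComponentConfig(BaseModel):
    """One razor-and-blade component: its own supply and use pattern."""

    supply: SupplyConfig
    use: UseConfig = Field(discriminator="type")


class ProductConfig(BaseModel):
    """Full description of one product: the unit of reach estimation."""

    product_name: str
    product_type: ProductType
    area: str = ""
    period: Period
    supply: Optional[SupplyConfig] = None
    use: Optional[UseConfig] = Field(default=None, discriminator="type")
    components: Optional[dict[Literal["razor", "blade"], ComponentConfig]] = None
    segments: Optional[list[SegmentConfig]] = None
    subgroups: Optional[list[SubgroupConfig]] = None
    coverage: Optional[CoverageConfig] = None

    @model_validator(mode="after")
    def _check_shape(self) -> "ProductConfig":
        if self.product_type is ProductType.razor_blade:
            if not self.components:
                raise ValueError("razor_blade products need a components mapping")
            if self.supply is not None or self.use is not None:
                raise ValueError(
                    "razor_blade products describe supply/use per component"
                )
            for name, comp in self.components.items():
                want = "durable" if name == "razor" else "fast_moving"
                if comp.use.type != want:
                    raise ValueError(f"component {name!r} needs a {want} use spec")
        else:
            if self.components is not None:
                raise ValueError("components are only for razor_blade products")
            if self.supply is None and self.coverage is None:
                raise ValueError("need a supply block and/or a coverage block")
            if self.supply is not None and self.use is None:
                raise ValueError("supply-based estimation needs a use block")
            if self.use is not None and self.use.type != self.product_type.value:
                raise ValueError(
                    f"use spec type {self.use.type!r} does not match "
                    f"product_type {self.product_type.value!r}"
                )
        if self.segments is not None:
            if self.product_type is not ProductType.fast_moving:
                raise ValueError("segments are defined for fast-moving products")
            share = sum(s.supply_share for s in self.segments)
            if not math.isclose(share, 1.0, abs_tol=1e-9):
                raise ValueError(f"segment supply shares must sum to 1 (got {share:g})")
        return self

    def segment_use(self, segment: SegmentConfig) -> FastMovingUseConfig:
        """The segment's use config: base use with the segment's overrides."""
        base = self.use.model_dump()
        if segment.use:
            base.update(segment.use)
        return FastMovingUseConfig.model_validate(base)

    def default_assumptions(self) -> list[AssumptionRecord]:
        """Assumption records for every default the config relied on."""
        records: list[AssumptionRecord] = []
        supplies = []
        if self.supply is not None:
            supplies.append(("supply", self.supply))
        for name, comp in (self.components or {}).items():
            supplies.append((f"{name}.supply", comp.supply))
        for prefix, sup in supplies:
            if "quality_factor" not in sup.model_fields_set:
                records.append(
                    AssumptionRecord(
                        element=f"{prefix}.quality_factor",
                        measure="b1",
                        basis="assumed",
                        value=1.0,
                    )
                )
            if "losses_factor" not in sup.model_fields_set:
                records.append(
                    AssumptionRecord(
                        element=f"{prefix}.losses_factor",
                        measure="c1",
                        basis="assumed",
                        value=1.0,
                    )
                )
            if "leakage_fraction" not in sup.model_fields_set:
                records.append(
                    AssumptionRecord(
                        element=f"{prefix}.leakage_fraction",
                        basis="assumed",
                        value=0.0,
                    )
                )
        return records


def load_config(path: Union[str, Path]) -> ProductConfig:
    """Load and validate a product config from a YAML/JSON file.

    Raises :class:`ConfigError` listing every validation failure at once.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    try:
        return ProductConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"invalid config {path} ({len(lines)} problem(s)):\n" + "\n".join(lines)
        ) from exc


_LEDGER_UNIT_GRAMS = {
    "grams": 1.0,
    "g": 1.0,
    "kilograms": GRAMS_PER_KG,
    "kg": GRAMS_PER_KG,
    "metric_tons": GRAMS_PER_MT,
    "mt": GRAMS_PER_MT,
}


def load_supply_ledger(
    path: Union[str, Path], period: Period
) -> tuple[float, int]:
    """Sum a dated supply ledger over the period.

    The CSV has columns ``date`` (ISO-8601), ``region``, ``quantity``,
    ``unit``. Returns (total grams inside the period, count of excluded
    out-of-period rows). Rows with unknown units or unparseable dates are
    reported together in a single :class:`LedgerRowError`.
    """
    try:
        df = pd.read_csv(path, dtype={"date": str, "region": str, "unit": str})
    except pd.errors.EmptyDataError:
        return 0.0, 0
    missing = {"date", "quantity", "unit"} - set(df.columns)
    if missing:
        raise LedgerRowError(f"ledger missing columns: {sorted(missing)}")
    bad_rows: list[str] = []
    total_g = 0.0
    excluded = 0
    for idx, row in df.iterrows():
        try:
            day = datetime.date.fromisoformat(str(row["date"]).strip())
        except ValueError:
            bad_rows.append(f"row {idx}: unparseable date {row['date']!r}")
            continue
        unit = str(row["unit"]).strip().lower()
        if unit not in _LEDGER_UNIT_GRAMS:
            bad_rows.append(f"row {idx}: unknown unit {row['unit']!r}")
            continue
        if not period.contains(day):
            excluded += 1
            continue
        total_g += float(row["quantity"]) * _LEDGER_UNIT_GRAMS[unit]
    if bad_rows:
        raise LedgerRowError(
            f"{len(bad_rows)} unusable ledger row(s)", rows=bad_rows
        )
    return total_g, excluded
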