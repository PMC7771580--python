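"""Scenario bounds and one-parameter sensitivity sweeps.

When a use-pattern or supply input is assumed rather than measured, the
honest report is a range: run the model under a conservative scenario
(e.g. recommended daily amount on every day — high per-consumer use, low
reach) and an optimistic one (e.g. a single trial use — low per-consumer
use, high reach), and present both bounds with the scenarios named, never
just "best/worst", so the direction of each assumption stays explicit.
"""

from __future__ import annotations

from typing import Any

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import ProductConfig
from .engine import ReachResult
from .errors import ConfigError
from .pipeline import estimate
from .rounding import FULL_PRECISION, RoundingPolicy


class ScenarioSpec(BaseModel):
    """A named set of config overrides, keyed by dotted config path."""

    name: str
    overrides: dict[str, Any] = Field(default_factory=dict)


class ScenarioRange(BaseModel):
    low_reach: int
    high_reach: int
    low_scenario: str
    high_scenario: str
    per_scenario: dict[str, ReachResult]

    @model_validator(mode="after")
    def _ordered(self) -> "ScenarioRange":
        if self.low_reach > self.high_reach:
            raise ValueError("low_reach must not exceed high_reach")
        return self


def apply_overrides(config: ProductConfig, overrides: dict[str, Any]) -> ProductConfig:
    """A copy of ``config`` with each dotted path replaced by its new value.

    Every path must already exist in the config (overriding a field that
    was never set is allowed only if the field exists in the schema dump);
    unknown paths raise :class:`ConfigError` naming the path. The result is
    re-validated in full.
    """
    data = config.model_dump()
    for path, value in overrides.items():
        node = data
        parts = path.split(".")
        for key_str in parts[:-1]:
            key: Any = key_str
            if isinstance(node, list):
                key = int(key_str)
                if not 0 <= key < len(node):
                    raise ConfigError(f"unknown override path: {path!r}")
            elif not (isinstance(node, dict) and key in node):
                raise ConfigError(f"unknown override path: {path!r}")
            node = node[key]
        last = parts[-1]
        if isinstance(node, list):
            idx = int(last)
            if not 0 <= idx < len(node):
                raise ConfigError(f"unknown override path: {path!r}")
            node[idx] = value
        elif isinstance(node, dict) and last in node:
            node[last] = value
        else:
            raise ConfigError(f"unknown override path: {path!r}")
    return ProductConfig.model_validate(data)


def run_scenarios(
    base_config: ProductConfig,
    scenarios: list[ScenarioSpec],
    policy: RoundingPolicy = FULL_PRECISION,
) -> ScenarioRange:
    """Estimate reach under each scenario and report the spanned range."""
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to bound a range")
    per: dict[str, ReachResult] = {}
    for spec in scenarios:
        cfg = apply_overrides(base_config, spec.overrides)
        per[spec.name] = estimate(cfg, policy)
    low = min(per, key=lambda n: per[n].total_reach)
    high = max(per, key=lambda n: per[n].total_reach)
    return ScenarioRange(
        low_reach=per[low].total_reach,
        high_reach=per[high].total_reach,
        low_scenario=low,
        high_scenario=high,
        per_scenario=per,
    )


def sensitivity_sweep(
    base_config: ProductConfig,
    path: str,
    values: list[Any],
    policy: RoundingPolicy = FULL_PRECISION,
) -> pd.DataFrame:
    """Total reach as one config path sweeps through a list of values.

    Returns a two-column table (value, total_reach), rows in input order.
    """
    rows = []
    for value in values:
        cfg = apply_overrides(base_config, {path: value})
        rows.append({"value": value, "total_reach": estimate(cfg, policy).total_reach})
    return pd.DataFrame(rows, columns=["value", "total_reach"])
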