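"""Seeded synthetic product configs with analytically known reach.

The generator draws a plausible product config (supply volumes, adjustment
factors, use patterns, optional segments) from documented ranges and
computes the expected full-precision reach with self-contained closed-form
arithmetic — deliberately *not* by calling the estimation pipeline — so the
pair (config, truth) can serve as an independent oracle in tests.

Ranges (uniform unless noted):
  period          start 2010-01..2020-12, 1..36 months
  sales volume    100..50,000 metric tons (fast-moving)
  unit count      1,000..1,000,000 (durable)
  quality/losses  0.8..1.0 each; leakage 0..0.2 (half the time defaulted)
  daily amount    10..300 g; 0..3 multipliers in 0.3..1.0; divisor 1..3
  use days        full period, or 1..period days
  users per unit  1..8, or a 2-4 bin household distribution with 1..10 users
  length of use   30..3,650 days
  segments        half the time, 2..3 shares normalised to 1
"""

from __future__ import annotations

import calendar
import math
import random
from typing import Optional

from pydantic import BaseModel, Field

from .config import ProductConfig


def _half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _period_days(start_y: int, start_m: int, n_months: int) -> int:
    """Day count by per-month enumeration (independent of Period)."""
    y, m, total = start_y, start_m, 0
    for _ in range(n_months):
        total += calendar.monthrange(y, m)[1]
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return total


class SyntheticTruth(BaseModel):
    """Closed-form expected reach for a generated config (full precision)."""

    expected_reach: int = Field(ge=0)
    component_reach: dict[str, int] = Field(default_factory=dict)
    period_days: int


def _draw_period(rng: random.Random) -> tuple[dict, int, int, int]:
    y = rng.randint(2010, 2020)
    m = rng.randint(1, 12)
    n = rng.randint(1, 36)
    end_y, end_m = y, m + n - 1
    end_y += (end_m - 1) // 12
    end_m = (end_m - 1) % 12 + 1
    cfg = {"start": f"{y:04d}-{m:02d}", "end": f"{end_y:04d}-{end_m:02d}"}
    return cfg, y, m, n


def _draw_supply(rng: random.Random, *, count: bool) -> tuple[dict, float]:
    """Supply config block and its effective quantity (grams or units)."""
    cfg: dict = {"mode": "sales_distribution"}
    if count:
        volume = float(rng.randint(1_000, 1_000_000))
        cfg.update(sales_volume=volume, unit="units")
        eff = volume
    else:
        volume = round(rng.uniform(100.0, 50_000.0), 2)
        cfg.update(sales_volume=volume, unit="metric_tons")
        eff = volume * 1_000_000.0
    quality = round(rng.uniform(0.8, 1.0), 3)
    losses = round(rng.uniform(0.8, 1.0), 3)
    cfg.update(quality_factor=quality, losses_factor=losses)
    eff *= quality * losses
    if rng.random() < 0.5:
        leakage = round(rng.uniform(0.0, 0.2), 3)
        cfg["leakage_fraction"] = leakage
        eff *= 1.0 - leakage
    return cfg, eff


def _draw_fast_use(rng: random.Random, pdays: int) -> tuple[dict, float, float]:
    """Use config block, adjusted daily grams, resolved use-days."""
    base = round(rng.uniform(10.0, 300.0), 1)
    divisor = round(rng.uniform(1.0, 3.0), 2)
    mults = [
        {"name": f"factor_{i}", "value": round(rng.uniform(0.3, 1.0), 3)}
        for i in range(rng.randint(0, 3))
    ]
    daily = base
    for m in mults:
        daily *= m["value"]
    daily /= divisor
    if rng.random() < 0.5:
        use_days: object = "period"
        days = float(pdays)
    else:
        days = round(rng.uniform(1.0, pdays), 1)
        use_days = days
    cfg = {
        "type": "fast_moving",
        "base_daily_amount": base,
        "multipliers": mults,
        "conversion_divisor": divisor,
        "use_days": use_days,
    }
    return cfg, daily, days


def _draw_durable_use(rng: random.Random, pdays: int) -> tuple[dict, float, float]:
    """Use config block, users-per-unit D, turnover E."""
    cfg: dict = {"type": "durable"}
    if rng.random() < 0.3:
        n_bins = rng.randint(2, 4)
        raw = [rng.uniform(0.1, 1.0) for _ in range(n_bins)]
        total = sum(raw)
        weights = [round(w / total, 6) for w in raw]
        weights[-1] = round(1.0 - sum(weights[:-1]), 6)
        users = [float(rng.randint(1, 10)) for _ in range(n_bins)]
        cfg["household_distribution"] = list(zip(weights, users))
        d = sum(w * u for w, u in zip(weights, users))
    else:
        d = float(rng.randint(1, 8))
        cfg["users_per_unit"] = d
    length = float(rng.randint(30, 3650))
    cfg["length_of_use_days"] = length
    e = 1.0 if length >= pdays else pdays / length
    return cfg, d, e


def generate_synthetic_config(
    seed: int, product_type: str = "fast_moving"
) -> tuple[ProductConfig, SyntheticTruth]:
    """Deterministic per seed; returns (config, closed-form truth)."""
    rng = random.Random(seed)
    period_cfg, y, m, n = _draw_period(rng)
    pdays = _period_days(y, m, n)
    raw: dict = {
        "product_name": f"synthetic-{product_type}-{seed}",
        "product_type": product_type,
        "area": "synthetic area",
        "period": period_cfg,
    }

    if product_type == "fast_moving":
        supply_cfg, eff = _draw_supply(rng, count=False)
        use_cfg, daily, days = _draw_fast_use(rng, pdays)
        raw.update(supply=supply_cfg, use=use_cfg)
        if rng.random() < 0.5:
            n_seg = rng.randint(2, 3)
            raw_shares = [rng.uniform(0.1, 1.0) for _ in range(n_seg)]
            total_share = sum(raw_shares)
            shares = [round(s / total_share, 6) for s in raw_shares]
            shares[-1] = round(1.0 - sum(shares[:-1]), 6)
            seg_days = [round(rng.uniform(1.0, pdays), 1) for _ in range(n_seg)]
            raw["segments"] = [
                {
                    "name": f"segment_{i}",
                    "supply_share": shares[i],
                    "use": {"use_days": seg_days[i]},
                }
                for i in range(n_seg)
            ]
            expected = sum(
                _half_up(eff * shares[i] / (daily * seg_days[i]))
                for i in range(n_seg)
            )
        else:
            expected = _half_up(eff / (daily * days))
        truth = SyntheticTruth(expected_reach=expected, period_days=pdays)

    elif product_type == "durable":
        supply_cfg, eff_units = _draw_supply(rng, count=True)
        use_cfg, d, e = _draw_durable_use(rng, pdays)
        raw.update(supply=supply_cfg, use=use_cfg)
        expected = _half_up(eff_units * d / e)
        truth = SyntheticTruth(expected_reach=expected, period_days=pdays)

    elif product_type == "razor_blade":
        components: dict = {}
        comp_truth: dict[str, int] = {}
        present = rng.choice([("razor",), ("blade",), ("razor", "blade")])
        if "razor" in present:
            supply_cfg, eff_units = _draw_supply(rng, count=True)
            use_cfg, d, e = _draw_durable_use(rng, pdays)
            components["razor"] = {"supply": supply_cfg, "use": use_cfg}
            comp_truth["razor"] = _half_up(eff_units * d / e)
        if "blade" in present:
            supply_cfg, eff = _draw_supply(rng, count=False)
            use_cfg, daily, days = _draw_fast_use(rng, pdays)
            components["blade"] = {"supply": supply_cfg, "use": use_cfg}
            comp_truth["blade"] = _half_up(eff / (daily * days))
        raw["components"] = components
        truth = SyntheticTruth(
            expected_reach=min(comp_truth.values()),
            component_reach=comp_truth,
            period_days=pdays,
        )
    else:
        raise ValueError(f"unknown product_type {product_type!r}")

    return ProductConfig.model_validate(raw), truth
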