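"""Durable-goods reach: latrines used by whole households.

A durable product reaches users_per_unit people per unit sold, divided by
turnover (units one consumer goes through in the period). Here 10,000
latrines are distributed over 5 years; household sizes vary (30% of
households have 4 users, 50% have 6, 20% have 9 → 6.0 users on average),
and a latrine outlives the period, so turnover is 1.
"""

from reachcalc import FULL_PRECISION, ProductConfig, estimate

cfg = ProductConfig.model_validate(
    {
        "product_name": "household latrines",
        "product_type": "durable",
        "period": {"start": "2020-01", "end": "2024-12"},
        "supply": {
            "mode": "sales_distribution",
            "sales_volume": 10_000,
            "unit": "units",
        },
        "use": {
            "type": "durable",
            "household_distribution": [[0.3, 4], [0.5, 6], [0.2, 9]],
            "length_of_use_days": 7300,  # ~20-year product life
        },
    }
)

result = estimate(cfg, FULL_PRECISION)
print(f"reach: {result.total_reach:,} people ({result.formula_used.value})")
print()
print("10,000 units × 6.0 users/unit ÷ 1 unit/consumer = 60,000 people:")
print("each latrine serves a whole household for the entire period.")
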