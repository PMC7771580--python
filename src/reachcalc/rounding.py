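"""Rounding policy: replication-mode vs full-precision arithmetic.

Published desk calculations typically chain *printed* (rounded)
intermediates: a daily amount printed to 0.1 g is what gets multiplied by
the use-day count, and the resulting per-person mass printed to the gram is
what divides the supply. Reproducing such a chain exactly requires rounding
each intermediate to its printed precision. ``replication`` mode does that;
``full_precision`` mode carries intermediates unrounded and rounds only the
final headcounts. Headcounts are always rounded half-up to the nearest
whole person in both modes.
"""

from __future__ import annotations

import enum
from decimal import ROUND_HALF_UP, Decimal

from pydantic import BaseModel

GRAMS_PER_KG = 1_000.0
GRAMS_PER_MT = 1_000_000.0

#: grams in 0.01 metric ton — the precision segment supplies are printed at
_SEGMENT_SUPPLY_STEP_G = GRAMS_PER_MT / 100.0


def round_half_up(value: float, step: float = 1.0) -> float:
    """Round ``value`` to the nearest multiple of ``step``, ties away from zero.

    Uses decimal arithmetic on the shortest repr of the float so that values
    like ``26781.300000000003`` (a float artefact of ``32.7 * 819``) round
    the way the printed number would.
    """
    d = Decimal(str(value)) / Decimal(str(step))
    return float(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP)) * step


def headcount(value: float) -> int:
    """Round a (non-negative) person count half-up to a whole person."""
    return int(round_half_up(value))


class RoundingMode(str, enum.Enum):
    replication = "replication"
    full_precision = "full_precision"


class RoundingPolicy(BaseModel):
    """Where in the pipeline intermediates are rounded.

    replication:    daily amount → 0.1 g; per-consumer period mass → 1 g;
                    per-segment supply → 0.01 metric ton; headcounts → 1.
    full_precision: only headcounts are rounded.
    """

    mode: RoundingMode = RoundingMode.full_precision

    model_config = {"frozen": True}

    @property
    def is_replication(self) -> bool:
        return self.mode is RoundingMode.replication

    def daily_amount(self, grams_per_day: float) -> float:
        if self.is_replication:
            return round_half_up(grams_per_day, 0.1)
        return grams_per_day

    def period_mass(self, grams: float) -> float:
        if self.is_replication:
            return round_half_up(grams, 1.0)
        return grams

    def segment_supply(self, grams: float) -> float:
        if self.is_replication:
            return round_half_up(grams, _SEGMENT_SUPPLY_STEP_G)
        return grams

    def headcount(self, value: float) -> int:
        return headcount(value)


REPLICATION = RoundingPolicy(mode=RoundingMode.replication)
FULL_PRECISION = RoundingPolicy(mode=RoundingMode.full_precision)
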