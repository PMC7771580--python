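"""Period arithmetic and effective-supply computation."""

import calendar
import datetime
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachcalc import (
    AdjustmentFactors,
    InconsistentFlowsError,
    Period,
    SupplyInputs,
    average_month_days,
    effective_supply,
    period_length_days,
    total_supply,
)
from reachcalc.errors import InvalidPeriodError


def brute_force_days(start_ym, end_ym):
    """Count days by walking the calendar one day at a time."""
    y, m = map(int, start_ym.split("-"))
    ey, em = map(int, end_ym.split("-"))
    day = datetime.date(y, m, 1)
    last = datetime.date(ey, em, calendar.monthrange(ey, em)[1])
    count = 0
    while day <= last:
        count += 1
        day += datetime.timedelta(days=1)
    return count


@pytest.mark.parametrize(
    "start,end,days",
    [
        ("2013-02", "2015-04", 819),  # the 27-month Brazil project window
        ("2021-01", "2021-01", 31),
        ("2016-02", "2016-02", 29),  # leap February
        ("2015-02", "2015-02", 28),
        ("2019-12", "2020-03", 122),  # spans a leap February
    ],
)
def test_period_length_known_values(start, end, days):
    assert period_length_days(Period(start=start, end=end)) == days
    assert brute_force_days(start, end) == days


def test_period_length_matches_brute_force_for_random_periods():
    rng = random.Random(20130201)
    for _ in range(200):
        y, m = rng.randint(1990, 2030), rng.randint(1, 12)
        n = rng.randint(1, 48)
        ey, em = y + (m + n - 2) // 12, (m + n - 2) % 12 + 1
        start, end = f"{y:04d}-{m:02d}", f"{ey:04d}-{em:02d}"
        p = Period(start=start, end=end)
        assert period_length_days(p) == brute_force_days(start, end)
        assert p.n_months == n


def test_period_end_before_start_rejected():
    with pytest.raises(InvalidPeriodError):
        Period(start="2015-04", end="2013-02")


def test_period_months_enumeration():
    p = Period(start="2013-11", end="2014-02")
    assert p.months() == ["2013-11", "2013-12", "2014-01", "2014-02"]


def test_average_month_days_is_the_printed_convention():
    assert average_month_days() == 30.4
    # the convention is a rounded 365/12, not any period-specific average:
    assert average_month_days() != pytest.approx(819 / 27)


class TestTotalSupply:
    def test_sales_mode_converts_metric_tons_to_grams(self):
        inputs = SupplyInputs(
            mode="sales_distribution", sales_volume=11174.56, unit="metric_tons"
        )
        assert total_supply(inputs) == pytest.approx(11_174_560_000.0)

    def test_flows_mode_nets_exports_and_imports_with_leakage(self):
        inputs = SupplyInputs(
            mode="production_flows",
            production=500,
            exports=200,
            imports=100,
            leakage_fraction=0.1,
            unit="grams",
        )
        assert total_supply(inputs) == pytest.approx(360.0)

    def test_everything_exported_gives_zero(self):
        inputs = SupplyInputs(
            mode="production_flows", production=100, exports=100, unit="grams"
        )
        assert total_supply(inputs) == 0.0

    def test_exports_exceeding_supply_rejected(self):
        inputs = SupplyInputs(
            mode="production_flows", production=100, exports=150, unit="grams"
        )
        with pytest.raises(InconsistentFlowsError):
            total_supply(inputs)

    def test_modes_agree_when_sales_equal_net_flows(self):
        flows = SupplyInputs(
            mode="production_flows",
            production=900,
            exports=300,
            imports=150,
            unit="kilograms",
        )
        sales = SupplyInputs(
            mode="sales_distribution", sales_volume=750, unit="kilograms"
        )
        assert total_supply(flows) == total_supply(sales)

    def test_mode_specific_fields_enforced(self):
        with pytest.raises(ValueError):
            SupplyInputs(mode="sales_distribution", production=10)
        with pytest.raises(ValueError):
            SupplyInputs(
                mode="sales_distribution", sales_volume=10, production=5
            )


class TestEffectiveSupply:
    def test_unit_factors_are_identity(self):
        es = effective_supply(11_174_560_000.0, AdjustmentFactors())
        assert es.quantity == 11_174_560_000.0

    def test_zero_quality_kills_supply(self):
        es = effective_supply(1e9, AdjustmentFactors(quality_factor=0.0))
        assert es.quantity == 0.0

    def test_factors_multiply(self):
        es = effective_supply(
            1000.0, AdjustmentFactors(quality_factor=0.9, losses_factor=0.8)
        )
        assert es.quantity == pytest.approx(720.0)

    @given(
        total=st.floats(min_value=0, max_value=1e12),
        q=st.floats(min_value=0, max_value=1),
        l=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_never_exceeds_unadjusted_total(self, total, q, l):
        es = effective_supply(
            total, AdjustmentFactors(quality_factor=q, losses_factor=l)
        )
        assert 0 <= es.quantity <= total

    @given(
        t1=st.floats(min_value=0, max_value=1e9),
        t2=st.floats(min_value=0, max_value=1e9),
        q=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_total(self, t1, t2, q):
        lo, hi = sorted([t1, t2])
        f = AdjustmentFactors(quality_factor=q)
        assert effective_supply(lo, f).quantity <= effective_supply(hi, f).quantity

    def test_factor_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AdjustmentFactors(quality_factor=1.2)
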