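"""Reach formulas: coverage route, fast-moving, durable, segments, bundles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachcalc import (
    FULL_PRECISION,
    REPLICATION,
    ConsumerSegment,
    CoverageInput,
    DoubleCountingError,
    EffectiveSupply,
    PerConsumerUse,
    ZeroUseError,
    coverage_from_reach,
    monthly_reach,
    razor_blade_reach,
    reach_durable,
    reach_fast_moving,
    reach_from_coverage,
    segmented_reach,
    subgroup_reach,
)
from reachcalc.engine import SubgroupSpec


def mass_supply(grams):
    return EffectiveSupply(quantity=grams, kind="mass")


def unit_supply(count):
    return EffectiveSupply(quantity=count, kind="count")


class TestCoverageRoute:
    def test_exact_half(self):
        res = reach_from_coverage(CoverageInput(coverage=0.5, population=1_000_000))
        assert res.total_reach == 500_000
        assert res.formula_used.value == "F1"

    def test_zero_coverage(self):
        res = reach_from_coverage(CoverageInput(coverage=0.0, population=123))
        assert res.total_reach == 0

    def test_headcount_rounds_half_up(self):
        res = reach_from_coverage(CoverageInput(coverage=0.327, population=12_345))
        assert res.total_reach == 4_037  # 4036.815

    def test_coverage_from_reach_is_the_ratio(self):
        assert coverage_from_reach(500_000, 1_000_000) == 0.5
        assert coverage_from_reach(0, 100) == 0.0
        assert coverage_from_reach(2_365_712, 200_000_000) == pytest.approx(
            2_365_712 / 200_000_000
        )

    def test_reach_exceeding_population_warns(self):
        with pytest.warns(UserWarning):
            assert coverage_from_reach(150, 100) == pytest.approx(1.5)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            coverage_from_reach(10, 0)

    @given(
        cov=st.floats(min_value=0, max_value=1),
        pop=st.integers(min_value=1, max_value=10**8),
    )
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_identity_within_one_person(self, cov, pop):
        reach = reach_from_coverage(
            CoverageInput(coverage=cov, population=pop)
        ).total_reach
        back = reach_from_coverage(
            CoverageInput(coverage=min(coverage_from_reach(reach, pop), 1.0),
                          population=pop)
        ).total_reach
        assert abs(back - reach) <= 1


class TestFastMoving:
    def test_brazil_single_segment_headcount(self):
        res = reach_fast_moving(
            mass_supply(11_174_560_000.0),
            PerConsumerUse(quantity=26_781.0),
            REPLICATION,
        )
        assert res.total_reach == 417_257

    def test_zero_supply(self):
        res = reach_fast_moving(
            mass_supply(0.0), PerConsumerUse(quantity=250.0), FULL_PRECISION
        )
        assert res.total_reach == 0

    def test_exact_division(self):
        res = reach_fast_moving(
            mass_supply(1000.0), PerConsumerUse(quantity=250.0), FULL_PRECISION
        )
        assert res.total_reach == 4

    def test_zero_use_rejected_at_type_level(self):
        with pytest.raises(ValueError):
            PerConsumerUse(quantity=0.0)

    @given(
        supply=st.floats(min_value=0, max_value=1e12),
        use1=st.floats(min_value=1, max_value=1e6),
        use2=st.floats(min_value=1, max_value=1e6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_weakly_decreasing_in_use(self, supply, use1, use2):
        lo, hi = sorted([use1, use2])
        r_lo = reach_fast_moving(
            mass_supply(supply), PerConsumerUse(quantity=lo), FULL_PRECISION
        ).total_reach
        r_hi = reach_fast_moving(
            mass_supply(supply), PerConsumerUse(quantity=hi), FULL_PRECISION
        ).total_reach
        assert r_hi <= r_lo


class TestDurable:
    def test_menstrual_cup_turnover(self):
        # 1000 cups, one user each, 5 cups per user over the period
        res = reach_durable(unit_supply(1000), 1, 5, FULL_PRECISION)
        assert res.total_reach == 200
        assert res.formula_used.value == "F2"

    def test_latrine_household(self):
        res = reach_durable(unit_supply(100), 5, 1, FULL_PRECISION)
        assert res.total_reach == 500

    def test_zero_units(self):
        assert reach_durable(unit_supply(0), 3, 1, FULL_PRECISION).total_reach == 0

    def test_mass_supply_rejected(self):
        with pytest.raises(ValueError):
            reach_durable(mass_supply(1000), 1, 1, FULL_PRECISION)

    def test_sub_unit_turnover_rejected(self):
        with pytest.raises(ValueError):
            reach_durable(unit_supply(1000), 1, 0.5, FULL_PRECISION)


class TestSegmentedReach:
    def brazil_segments(self):
        return [
            ConsumerSegment(
                name="repeat", supply_share=0.82,
                per_consumer_use=PerConsumerUse(quantity=26_781.0),
            ),
            ConsumerSegment(
                name="trial", supply_share=0.18,
                per_consumer_use=PerConsumerUse(quantity=994.0),
            ),
        ]

    def test_brazil_repeat_trial_split(self):
        res = segmented_reach(
            mass_supply(11_174_560_000.0), self.brazil_segments(), REPLICATION
        )
        assert res.segment_reach == {"repeat": 342_151, "trial": 2_023_561}
        assert res.total_reach == 2_365_712

    def test_single_segment_reduces_to_plain_estimate(self):
        seg = [
            ConsumerSegment(
                name="all", supply_share=1.0,
                per_consumer_use=PerConsumerUse(quantity=26_781.0),
            )
        ]
        res = segmented_reach(mass_supply(11_174_560_000.0), seg, REPLICATION)
        plain = reach_fast_moving(
            mass_supply(11_174_560_000.0),
            PerConsumerUse(quantity=26_781.0),
            REPLICATION,
        )
        assert res.total_reach == plain.total_reach

    def test_equal_segments_split_reach_evenly(self):
        supply = mass_supply(10_000_000.0)
        use = PerConsumerUse(quantity=123.0)
        segs = [
            ConsumerSegment(name=f"s{i}", supply_share=0.5, per_consumer_use=use)
            for i in range(2)
        ]
        split = segmented_reach(supply, segs, FULL_PRECISION).total_reach
        single = reach_fast_moving(supply, use, FULL_PRECISION).total_reach
        assert abs(split - single) <= 2

    def test_shares_must_sum_to_one(self):
        segs = self.brazil_segments()
        segs[0] = segs[0].model_copy(update={"supply_share": 0.5})
        with pytest.raises(ValueError):
            segmented_reach(mass_supply(1e9), segs, FULL_PRECISION)

    def test_totals_match_independent_per_segment_computation(self):
        """Brute-force oracle over 500 random segmented configurations."""
        rng = random.Random(417257)
        for _ in range(500):
            supply = rng.uniform(1e6, 1e11)
            n = rng.randint(1, 4)
            raw = [rng.uniform(0.1, 1.0) for _ in range(n)]
            shares = [x / sum(raw) for x in raw]
            shares[-1] = 1.0 - sum(shares[:-1])
            uses = [rng.uniform(10, 1e5) for _ in range(n)]
            segs = [
                ConsumerSegment(
                    name=f"s{i}", supply_share=shares[i],
                    per_consumer_use=PerConsumerUse(quantity=uses[i]),
                )
                for i in range(n)
            ]
            res = segmented_reach(mass_supply(supply), segs, FULL_PRECISION)
            expected = sum(
                int((supply * shares[i] / uses[i]) + 0.5) for i in range(n)
            )
            assert res.total_reach == expected
            assert res.total_reach == sum(res.segment_reach.values())


class TestSubgroups:
    def test_brazil_subpopulations(self):
        counts = subgroup_reach(
            2_365_712,
            [
                SubgroupSpec(name="women", population_fraction=0.2814),
                SubgroupSpec(name="children", population_fraction=0.0654),
                SubgroupSpec(name="lower_ses", population_fraction=0.741),
            ],
            REPLICATION,
        )
        assert counts == {
            "women": 665_711,
            "children": 154_718,
            "lower_ses": 1_752_993,
        }

    def test_full_fraction_returns_total(self):
        counts = subgroup_reach(
            98_765, [SubgroupSpec(name="all", population_fraction=1.0)], FULL_PRECISION
        )
        assert counts == {"all": 98_765}

    def test_overlapping_subgroups_may_exceed_total_jointly(self):
        counts = subgroup_reach(
            100,
            [
                SubgroupSpec(name="a", population_fraction=0.9),
                SubgroupSpec(name="b", population_fraction=0.9),
            ],
            FULL_PRECISION,
        )
        assert sum(counts.values()) == 180  # overlap is allowed


class TestRazorBlade:
    def razor(self, n):
        return reach_durable(unit_supply(n), 1, 1, FULL_PRECISION)

    def blade(self, n):
        return reach_fast_moving(
            mass_supply(float(n)), PerConsumerUse(quantity=1.0), FULL_PRECISION
        )

    def test_single_component_stands_in(self):
        res = razor_blade_reach(self.razor(10_000), None)
        assert res.total_reach == 10_000
        assert res.component_reach == {"razor": 10_000}

    def test_both_components_take_conservative_minimum(self):
        res = razor_blade_reach(self.razor(10_000), self.blade(8_000))
        assert res.total_reach == 8_000
        assert res.component_reach == {"razor": 10_000, "blade": 8_000}

    def test_identical_components(self):
        res = razor_blade_reach(self.razor(5_000), self.blade(5_000))
        assert res.total_reach == 5_000

    def test_no_components_rejected(self):
        with pytest.raises(ValueError):
            razor_blade_reach(None, None)


class TestMonthlySeries:
    def test_monthly_values_available_but_sum_refused(self):
        series = monthly_reach(
            {"2013-02": mass_supply(1e8), "2013-03": mass_supply(2e8)},
            PerConsumerUse(quantity=994.0),
            FULL_PRECISION,
        )
        by_month = series.reach_by_month()
        assert set(by_month) == {"2013-02", "2013-03"}
        assert all(v > 0 for v in by_month.values())
        with pytest.raises(DoubleCountingError):
            series.total()
        with pytest.raises(DoubleCountingError):
            series.sum()


class TestConservation:
    @given(
        supply=st.floats(min_value=1, max_value=1e12),
        use=st.floats(min_value=0.1, max_value=1e6),
    )
    @settings(max_examples=300, derandomize=True)
    def test_reach_times_use_recovers_supply_before_rounding(self, supply, use):
        """reach (pre-rounding) × per-consumer use = effective supply."""
        unrounded = supply / use
        assert unrounded * use == pytest.approx(supply, rel=1e-9)
        rounded = reach_fast_moving(
            mass_supply(supply), PerConsumerUse(quantity=use), FULL_PRECISION
        ).total_reach
        assert abs(rounded - unrounded) <= 0.5
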