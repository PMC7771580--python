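# Methods

## The reach model

`reachcalc` implements a deterministic arithmetic model that converts
product supply-chain data and consumer use patterns into a headcount of
individuals reached. It is not a statistical model: there is no likelihood,
no fitting, and no stochastic component. Its value is standardization — a
single, explicit chain from supply volumes to people, with every assumption
recorded — and its correctness rests on unit discipline, calendar
arithmetic and rounding behaviour, which is where the engineering effort
went.

Definitions. *Reach* is the estimated number of individuals in a defined
area using a defined quantity of the product over a defined period; it is
an absolute headcount. *Coverage* is the same quantity expressed as a
proportion of a stated population. The two convert into each other by
multiplying or dividing by the population, and the package keeps the
scope of a coverage figure (total population vs target group) attached to
it so the two cannot be mixed.

Supply side. Total supply comes either from sales/distribution volumes
(preferred, being closer to the consumer) or from
production − exports + imports; a leakage fraction removes supply leaving
the area, and contraband entering the area is entered as ordinary imports
(identical arithmetic role). Effective supply multiplies by a quality
factor and a post-production losses factor, both proportions in [0, 1]
defaulting to 1 (the maximum-reach assumption, recorded in the ledger when
defaulted).

Demand side, fast-moving: per-consumer use over the period is an adjusted
daily amount times a use-day count. The daily amount is a base figure
(measured, f1, or recommended, f2) times any number of named share
multipliers in [0, 1] and divided by a unit-conversion ratio. Per-capita
consumption figures are treated as per-consumer; where only a fraction of
the population consumes the product, that fraction is expressed as just
another multiplier, keeping the assumption explicit and in the ledger.

Demand side, durable: reach per unit is users-per-unit (a scalar or the
weighted mean of a household-size distribution) divided by turnover, the
number of units one consumer goes through in the period. Turnover is
`period ÷ length of use`, floored at 1 when the product outlives the
period, and kept unrounded — it is a rate, not a printed figure. The
division by turnover deserves a note: one source sentence describes D as
"multiplied by" E, but the worked example accompanying it (a consumer who
goes through five one-year units in a five-year period) only makes sense if
a higher turnover *reduces* the headcount a unit count supports.
Dimensional analysis agrees (units × persons/unit ÷ units/person =
persons), so the package divides and documents the discrepancy here.

Razor-and-blade: each component is estimated with its own model. When both
are present the combined estimate is the minimum of the two — no
combination rule is established in the field, and the minimum is the
conservative bound (a person is reached by the bundle only if reached by
both parts); both raw component values are always reported. With one
component, that component stands in for the bundle.

Segments and subgroups. Consumer segments (e.g. repeat vs trial buyers)
partition the *supply* by share — shares must sum to 1 — and each segment
has its own use intensity; segment headcounts are computed independently
and summed, which assumes segments are disjoint sets of people. Subgroup
allocation multiplies the total by each group's population fraction,
assuming homogeneous use across subgroups (ledger-recorded); fractions are
deliberately *not* required to sum to 1 because real subgroups of interest
(women of reproductive age, young children, socioeconomic classes) overlap.

Monthly series. Reach can be computed per month for trend review, but the
`MonthlyReachSeries` container raises `DoubleCountingError` on any attempt
to total it: an individual using the product in several months would be
counted once per month. Period reach must come from supply aggregated over
the whole period.

## Rounding policies

Headcounts are always rounded half-up to a whole person, in both policies.
Half-up (ties away from zero) was chosen because it reproduces every
headcount in the packaged worked example from the unrounded quotients;
banker's rounding does not.

`replication` mode additionally rounds chain intermediates to the precision
such figures are conventionally printed at: adjusted daily amount to 0.1 g,
per-consumer period mass to 1 g, per-segment supply to 0.01 metric ton.
This exists because published desk calculations chain their *printed*
intermediates — 32.7 g/day × 819 days = 26,781 g is only reproducible if
32.7012 is rounded before the multiplication. `full_precision` (the
default, and the right choice for new analyses) carries everything
unrounded until the final headcount. Rounding is done in decimal on the
shortest float repr, so artefacts like 26781.300000000003 round the way
the printed number would.

Two calendar constants coexist by design: the period day count is exact
calendar arithmetic (whole months, first day of start month through last
day of end month, leap years honoured), while "one month" of use is the
conventional 30.4 days (365/12 rounded to one decimal). These are not
reconciled — 819/27 ≈ 30.33 ≠ 30.4 — because each is used where practice
uses it, and the packaged case depends on both.

Periods are restricted to whole calendar months. No convention for partial
months is established, and the day-count anchor (819 days for the
27-month packaged case) only holds under the whole-month reading.

## Units

The canonical internal mass unit is the gram; configs may state volumes in
g, kg or metric tons (1 MT = 10⁶ g). Durables use unit counts throughout.
`EffectiveSupply` carries a `kind` tag ("mass"/"count") and the durable
formula refuses mass-kind supplies, preventing silent unit errors.

## Configuration and the assumptions ledger

A product config is one YAML/JSON document validated by pydantic; every
problem is reported at once. Each estimate carries an assumptions ledger:
which measure stood behind each element (sales a1 vs flows a2; measured f1
vs recommended f2; etc.), every default applied (factors defaulting to 1,
leakage to 0), and structural assumptions (subgroup homogeneity, the
razor-blade minimum rule). The ledger is part of the result object and of
every written report, because a reach estimate is only interpretable
together with the assumptions that produced it.

Scenario analysis is deliberately minimal: named scenarios (never bare
"best/worst" — the direction of an assumption should stay visible; the
conservative label belongs to the recommended-use, lowest-reach scenario)
and one-dimensional sensitivity sweeps. Reach responds monotonically to
every single parameter, so one-dimensional reasoning is faithful;
multi-parameter grids and Monte-Carlo propagation are out of scope, since
uncertainty here is about discrete assumptions, not sampling error.

## Synthetic configs and what the tests show

`generate_synthetic_config(seed, product_type)` draws a config from
documented ranges (supply 100–50,000 MT or 10³–10⁶ units; factors 0.8–1;
leakage 0–0.2; daily amounts 10–300 g; 0–3 multipliers in 0.3–1;
conversion divisors 1–3; use lengths up to the period; 1–36-month periods;
optional 2–3-way segment splits) and bundles the analytically known
full-precision reach, computed with self-contained closed-form arithmetic
that never calls the estimation pipeline. The ranges are meant to span
realistic staple-food, supplement and durable programs rather than stress
numerical extremes.

The generator emulates *configuration diversity*, not data messiness: it
produces internally consistent inputs with exact arithmetic truths. Passing
the oracle suite therefore shows the pipeline computes the model correctly
across product types and parameter ranges; it says nothing about whether a
real program's sales data are complete, its leakage negligible, or its
consumption survey representative — those remain input-quality questions
the ledger is designed to keep visible.

The packaged Brazil fortified-rice case is the external anchor: every
printed intermediate and headcount of that published calculation is
reproduced exactly in replication mode (see `tests/test_acceptance.py` and
`scripts/acceptance.py`). Its monthly supply ledger is synthetic — the
monthly breakdown was never published — distributing the period total
uniformly across the 27 months solely to exercise ledger ingestion; its
period sum is exact.

## Numerical choices and edge cases

* Half-up headcount rounding via `decimal` on `str(float)`; no binary
  `.5`-tie surprises.
* Zero supply is a valid input (reach 0); zero per-consumer use, zero
  population and negative flow balances raise typed errors rather than
  returning infinities.
* `coverage_from_reach` returns the unclamped ratio and warns when it
  exceeds 1, so triangulation surfaces inconsistencies instead of hiding
  them.
* Scenario overrides must name existing config paths; overridden values
  re-validate against the full schema.
* Reports are byte-stable (sorted keys, fixed formats) so archived runs
  can be diffed.

## Known limitations

Point estimates only — no uncertainty intervals beyond named scenario
bounds. No intra-period seasonality of consumption. No geospatial
structure beyond a free-text area label. No survey-microdata ingestion:
only summary parameters enter. Reach measures exposure, not impact; the
package computes who the supply could cover at the stated use pattern,
which is an input to — not a substitute for — outcome evaluation.

## Problem sizes in the shipped checks

The test suite and acceptance script use the packaged 27-month case, 200
brute-force calendar checks, 500 random segment configurations, ~1,000
synthetic-oracle seeds and ~600 acceptance-time oracle configurations;
everything is exact arithmetic on scalars, so the whole battery runs in a
few seconds.
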