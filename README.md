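# reachcalc

Estimate **product reach** — the number of individuals in a defined area
using a defined quantity of a product over a defined period — from the data
social-impact programs actually have: supply-chain volumes and consumer use
patterns, rather than beneficiary registers or expensive coverage surveys.

Programs that introduce a health or social product (fortified foods,
supplements, bed nets, latrines, menstrual cups, water filters…) need a
headcount of people reached to manage delivery and report to funders, but
in data-scarce settings nobody registers individual beneficiaries. What *is*
usually available is how much product moved: sales or distribution volumes,
or production − exports + imports. `reachcalc` converts those volumes into
people, with every assumption recorded.

## The model

Reach can be estimated two ways, and triangulated when both are possible:

* **Coverage route (F1):** `reach = coverage × target population` — when a
  coverage survey exists.
* **Supply route:** start from total supply *A* in the area and period,
  adjust by a quality factor *b₁* ∈ [0, 1] (share meeting specification)
  and a post-production losses factor *c₁* ∈ [0, 1], giving the effective
  supply `F4 = A · b₁ · c₁`. Then:
  * **Fast-moving goods (F3):** per-consumer use over the period is
    `F6 = (daily amount) × (use days)`, where the daily amount may be
    narrowed by share multipliers and a unit-conversion divisor;
    `reach = F4 / F6`.
  * **Durable goods (F2):** with *D* users per unit and turnover
    `E = max(1, period ÷ length of use)` units per consumer,
    `reach = F4 · D / E`.
  * **Razor-and-blade products** estimate each component separately; the
    combined reach is the conservative minimum of the two.

Consumer segments (e.g. repeat vs trial purchasers) split the supply by
share, each with its own use intensity; subgroup headcounts (e.g. women of
reproductive age) are allocated proportionally assuming homogeneous use.
Monthly reach series are supported for trend review, but the package
*refuses* to sum them into a period total — that would double-count people
who use the product in several months.

Two rounding policies are provided: `full_precision` (default; only final
headcounts are rounded, half-up) and `replication`, which also rounds
intermediates to the precision such figures are conventionally printed at
(daily amount to 0.1 g, per-consumer mass to 1 g, segment supply to 0.01
metric ton) so that a published desk calculation can be reproduced digit
for digit.

## Worked example

The packaged case: fortified rice introduced in Brazil, February 2013 –
April 2015 (27 months, 819 days), 11,174.56 metric tons dispatched, average
cooked-rice intake 160.3 g/person/day, 85% eaten at home, 60% of home rice
fortified, cooked→dry conversion ÷ 2.5; 82% of supply bought by repeat
consumers (use all 819 days), 18% by trial consumers (use ≈ one month,
30.4 days).

```sh
python examples/brazil_fortified_rice.py
```

prints

```
period: 2013-02 .. 2015-04 = 819 days
total reach: 2,365,712 people
  repeat_consumers: 342,151
  trial_consumers: 2,023,561
  subgroup women_15_49y: 665,711
  subgroup children_6m_5y: 154,718
  subgroup lower_ses_classes_cde: 1,752,993
```

The daily fortified-rice amount works out to 32.7 g, so a repeat consumer
accounts for 26.781 kg over the period and a trial consumer for 994 g; the
supply divided by those masses gives the segment headcounts, and the
subgroup rows allocate the 2.37 million total by each group's population
fraction (28.14%, 6.54%, 74.1%).

The same result from the command line:

```sh
reachcalc fixture brazil --out fixtures/
reachcalc estimate fixtures/brazil_fortified_rice.yaml --policy replication
```

Other examples in `examples/`: durable goods with a household-size
distribution (`durable_latrines.py`), scenario bounds when use frequency is
assumed (`scenario_bounds.py`), supply-vs-survey triangulation
(`coverage_triangulation.py`), and a razor-and-blade product
(`razor_blade_water_filter.py`).

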