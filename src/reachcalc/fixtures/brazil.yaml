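# Fortified rice in Brazil, Feb 2013 – Apr 2015: the worked case this
# package replicates. All figures are the published project inputs.
product_name: Fortified rice (Brazil)
product_type: fast_moving
area: Brazil, regions served by the partner rice miller
period:
  start: "2013-02"
  end: "2015-04"
  label: product introduction through last shared supply data
supply:
  mode: sales_distribution        # monthly sales to retailers (a1)
  sales_volume: 11174.56
  unit: metric_tons
  quality_factor: 1.0             # independent testing met regulations (b1)
  losses_factor: 1.0              # negligible post-production losses (c1)
use:
  type: fast_moving
  base_daily_amount: 160.3        # g cooked rice per capita per day (f1)
  amount_basis: measured
  multipliers:
    - {name: share_of_rice_eaten_at_home, value: 0.85}
    - {name: fortified_share_of_home_rice, value: 0.60}
  conversion_divisor: 2.5         # cooked -> dry mass
  use_days: period                # staple: consumed every day (g1)
  frequency_basis: measured
segments:
  - name: repeat_consumers        # 82% of buyers purchase repeatedly
    supply_share: 0.82
  - name: trial_consumers         # try it for about one month (30.4 days)
    supply_share: 0.18
    use: {use_days: 30.4}
subgroups:
  - {name: women_15_49y, population_fraction: 0.2814}
  - {name: children_6m_5y, population_fraction: 0.0654}
  - {name: lower_ses_classes_cde, population_fraction: 0.741}
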