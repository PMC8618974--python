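# Versioned numeric constants for gas-exchange energy conversion.
version: "2024.1"
weir:
  # Abbreviated Weir form without urinary-nitrogen correction:
  #   REE [kcal/day] = minutes_per_day * (vo2_coef * VO2 + vco2_coef * VCO2)
  # with gases in L/min.  Weir JB, J Physiol 1949;109:1-9 (abbreviated form).
  vo2_coef: 3.941
  vco2_coef: 1.106
  minutes_per_day: 1440
mehta:
  # VCO2-only estimator for mechanically ventilated children:
  #   REE [kcal/day] = kcal_per_l_co2 * VCO2 [L/min] * 1440
  # Mehta NM et al., Crit Care Med 2015;43(7):1498-1505.
  kcal_per_l_co2: 5.534
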