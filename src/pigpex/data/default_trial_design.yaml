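# Four total-collection balance experiments spanning 15-93 kg pigs.
# Each: 12 barrows x 2 periods (9 d each: 5 d adaptation + 4 d collection),
# 3 diets in a quadruplicated 3x2 incomplete Latin square -> 24 records.
# diet_p_levels_pct are analyzed total-P concentrations (% as-fed).
# allowance_basis: BW on which the daily feed allowance percentage is set.
experiments:
  - label: Exp1
    n_pigs: 12
    periods: 2
    initial_bw_mean_kg: 15.2
    initial_bw_sd_kg: 0.7
    final_bw_mean_kg: 24.7
    final_bw_sd_kg: 1.4
    feed_allowance_frac_of_bw: 0.060
    allowance_basis: experiment_initial
    diet_p_levels_pct: [0.445, 0.495, 0.460]
  - label: Exp2
    n_pigs: 12
    periods: 2
    initial_bw_mean_kg: 29.9
    initial_bw_sd_kg: 1.8
    final_bw_mean_kg: 46.7
    final_bw_sd_kg: 2.7
    feed_allowance_frac_of_bw: 0.045
    allowance_basis: period_initial
    diet_p_levels_pct: [0.555, 0.540, 0.525]
  - label: Exp3
    n_pigs: 12
    periods: 2
    initial_bw_mean_kg: 50.2
    initial_bw_sd_kg: 2.2
    final_bw_mean_kg: 70.0
    final_bw_sd_kg: 4.2
    feed_allowance_frac_of_bw: 0.040
    allowance_basis: period_initial
    diet_p_levels_pct: [0.500, 0.480, 0.485]
  - label: Exp4
    n_pigs: 12
    periods: 2
    initial_bw_mean_kg: 78.2
    initial_bw_sd_kg: 3.7
    final_bw_mean_kg: 92.6
    final_bw_sd_kg: 4.5
    feed_allowance_frac_of_bw: 0.030
    allowance_basis: period_initial
    diet_p_levels_pct: [0.450, 0.420, 0.415]
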