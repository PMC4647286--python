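# Decision-model point values and PSA mean/SE pairs.
# Branch costs are the covariate-standardised (marginally predicted) costs of
# each treatment-decision x MACE cell; trial QALYs enter unstructured per arm.

treatment_probs:
  ffr: [0.23, 0.71, 0.06]
  standard: [0.13, 0.80, 0.07]
treatment_prob_ses:
  ffr: [0.03, 0.02, 0.02]
  standard: [0.02, 0.01, 0.02]

mace_mt: {mean: 0.09, se: 0.01}
or_pci: {mean: 1.01, ci_low: 0.35, ci_high: 2.86}
or_cabg: {mean: 3.80, ci_low: 0.98, ci_high: 14.62}

branch_costs:                    # GBP, decision x MACE status
  MT_mace: {mean: 9622.0, se: 864.0}
  PCI_mace: {mean: 14894.0, se: 589.0}
  CABG_mace: {mean: 21851.0, se: 1984.0}
  MT_no_mace: {mean: 5819.0, se: 139.0}
  PCI_no_mace: {mean: 7204.0, se: 72.0}
  CABG_no_mace: {mean: 17774.0, se: 482.0}

branch_qalys:                    # trial-period QALYs per arm (SE from 95% CI width / 3.92)
  standard: {mean: 0.801, se: 0.01786}
  ffr: {mean: 0.82, se: 0.01480}

wire_cost_ffr: {mean: 279.0, se: 3.57}   # SE from 95% CI (273-287) width / 3.92

life_expectancy_mace: {mean: 10.70, se: 2.20}     # additional years beyond year 1
life_expectancy_no_mace: {mean: 5.96, se: 1.30}
swap_life_expectancy: false

annual_cost_post_year1: {mean: 423.0, se: 55.0}
mace_utility_decrement: {mean: -0.05, se: 0.04}

utility_schedule: {base: 0.82, base_age: 63.0, slope_per_year: 0.003}
discount_rate: 0.035
starting_age: 62.0
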