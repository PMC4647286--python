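# Default synthetic-trial calibration: arm-level treatment-decision
# probabilities, MACE odds model, EQ-5D utility / QALY targets, per-category
# mean cost targets (2014 GBP) and EQ-5D missingness rates.

n_per_arm: 176
seed: 20140101

treatment_probs:
  ffr: [0.23, 0.71, 0.06]        # MT, PCI, CABG
  standard: [0.13, 0.80, 0.07]
treatment_prob_ses:
  ffr: [0.03, 0.02, 0.02]
  standard: [0.02, 0.01, 0.02]

mace_baseline: 0.09              # marginal MACE probability under MT
mace_or_pci: 1.01
mace_or_cabg: 3.80
mace_covariate_effects: {utility: -0.5, age: 0.02, sex: 0.0, copd: 0.5}
mace_event_split: [0.1, 0.3, 0.1, 0.5]   # death, MI, stroke, revascularisation
death_time_range: [0.0, 1.0]

covariates:
  age_mean: 62.0
  age_sd: 11.0
  age_bounds: [30.0, 95.0]
  p_male: 0.74
  p_smoker: 0.30
  p_prior_pci: 0.12
  p_copd: 0.11

utility_targets:                 # survivor means at 0 / 6 / 12 months
  ffr: [0.78, 0.83, 0.83]
  standard: [0.80, 0.83, 0.80]
utility_sd: 0.2
utility_corr: 0.5
qaly_targets: {ffr: 0.82, standard: 0.801}
qaly_adjust_times:
  ffr: [0.5]
  standard: [0.5, 1.0]

missingness_rates: [0.17, 0.24]  # 6-month, 12-month EQ-5D responses
missingness_mode: mcar

category_cost_targets:
  standard:
    pressure_wire: 0.0
    pci: 837.0
    cabg: 346.0
    medications: 59.0
    cath_lab: 1806.0
    length_of_stay: 4435.0
    other_procedures: 125.0
    events: 956.0
  ffr:
    pressure_wire: 279.0
    pci: 766.0
    cabg: 314.0
    medications: 49.0
    cath_lab: 1864.0
    length_of_stay: 4104.0
    other_procedures: 134.0
    events: 713.0

category_item_weights:
  pci:
    guiding_catheter: 0.15
    guidewire: 0.10
    balloon: 0.20
    des_stent: 0.45
    bms_stent: 0.10
  medications:
    tirofiban: 0.35
    bivalirudin: 0.30
    clopidogrel_month: 0.35
  length_of_stay:
    ccu_day: 0.35
    itu_day: 0.25
    ward_day: 0.40
  other_procedures:
    echo: 0.60
    xray: 0.20
    oct: 0.10
    ivus: 0.10

background_event_weights: {rehospitalisation: 0.9, severe_bleed: 0.1}

wires_per_patient: 1.03
adenosine_vials_mean: 0.0
cathlab_gamma_shape: 2.0
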