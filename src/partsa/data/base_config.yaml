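# Base-case model inputs for first-line sugemalimab + platinum-doublet
# chemotherapy vs chemotherapy in metastatic NSCLC (Chinese health-system
# perspective; all amounts USD, converted at 1 USD = 6.71 CNY).
settings:
  cycle_days: 21
  horizon_years: 10
  discount_rate_annual: 0.05
  discount_rate_range: [0.0, 0.08]
  half_cycle_correction: false
  wtp_per_qaly: 36203.88
  squamous_fraction: 0.4
  pd_crossover_cap_cycles: null

curves:
  sugemalimab:
    pfs: {family: loglogistic, params: [1.6637, 9.3549]}
    os: {family: loglogistic, params: [1.3722, 24.9818]}
  placebo:
    pfs: {family: loglogistic, params: [1.9645, 5.3347]}
    os: {family: lognormal, params: [2.8289, 0.9785]}

dosing:
  bsa_m2: 1.72
  gfr_ml_min: 70
  carboplatin_auc: 5
  pemetrexed_mg_per_m2: 500
  paclitaxel_mg_per_m2: 175
  docetaxel_mg_per_m2: 75
  sugemalimab_mg_flat: 1200
  induction_cycles: 4
  max_treatment_cycles: 35

vials:
  sugemalimab_vial_mg: 600
  carboplatin_vial_mg: 100
  pemetrexed_vial_mg: 100
  paclitaxel_vial_mg: 30
  docetaxel_vial_mg: 20

# Each priced input: base value, one-way range, PSA distribution family.
prices:
  sugemalimab_per_vial: {base: 1844.26, low: 922.13, high: 1844.26, dist: gamma}
  carboplatin_per_vial: {base: 13.39, low: 10.71, high: 16.06, dist: gamma}
  pemetrexed_per_vial: {base: 330.23, low: 264.18, high: 396.27, dist: gamma}
  paclitaxel_per_vial: {base: 51.39, low: 41.12, high: 61.67, dist: gamma}
  docetaxel_per_vial: {base: 96.65, low: 77.32, high: 115.97, dist: gamma}
  hospital_per_cycle: {base: 72.43, low: 57.94, high: 86.91, dist: gamma}
  followup_per_cycle: {base: 199.55, low: 159.64, high: 239.46, dist: gamma}
  bsc_per_cycle: {base: 320.84, low: 256.67, high: 385.01, dist: gamma}
  sae_cost_sugemalimab: {base: 23.57, low: 18.86, high: 28.28, dist: gamma}
  sae_cost_placebo: {base: 23.81, low: 19.05, high: 28.57, dist: gamma}

utilities:
  pfs: {base: 0.804, low: 0.536, high: 0.840, dist: beta}
  pd: {base: 0.321, low: 0.031, high: 0.473, dist: beta}

# Disutilities are negative; ranges given on the signed scale.
disutilities:
  neutropenia: {base: -0.20, low: -0.50, high: -0.15, dist: beta}
  nausea_vomiting: {base: -0.12, low: -0.29, high: -0.06, dist: beta}
  alopecia: {base: -0.06, low: -0.26, high: -0.06, dist: beta}
  rash: {base: -0.10, low: -0.19, high: -0.10, dist: beta}
  fatigue: {base: -0.07, low: -0.49, high: -0.07, dist: beta}
  diarrhoea: {base: -0.07, low: -0.35, high: -0.06, dist: beta}

# Grade >=3 adverse events with >=10% incidence, per arm.
sae_probabilities:
  sugemalimab:
    neutropenia: {base: 0.3250, low: 0.2600, high: 0.3900, dist: beta}
    nausea_vomiting: {base: 0.0160, low: 0.0128, high: 0.0192, dist: beta}
    alopecia: {base: 0.0030, low: 0.0024, high: 0.0036, dist: beta}
    rash: {base: 0.0060, low: 0.0048, high: 0.0072, dist: beta}
    fatigue: {base: 0.0090, low: 0.0072, high: 0.1080, dist: beta}
    diarrhoea: {base: 0.0090, low: 0.0072, high: 0.1080, dist: beta}
  placebo:
    neutropenia: {base: 0.3330, low: 0.2664, high: 0.3996, dist: beta}
    nausea_vomiting: {base: 0.0250, low: 0.0200, high: 0.0300, dist: beta}
    fatigue: {base: 0.0060, low: 0.0048, high: 0.0072, dist: beta}

# Post-progression treatment mix per arm (fractions of PD cohort).
subsequent:
  sugemalimab: {new_anticancer: 0.531, crossover_immunotherapy: 0.056, best_supportive_care: 0.413}
  placebo: {new_anticancer: 0.251, crossover_immunotherapy: 0.277, best_supportive_care: 0.472}

psa:
  n_draws: 1000
  wtp_max: 400000
  wtp_step: 2000
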