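# Base-case parameter set: third-line apatinib vs supportive care in
# chemotherapy-refractory metastatic gastric cancer, Chinese health-insurance
# (payer) perspective, 2015 US dollars.
schema: 1

config:
  cycle_length: 1
  cycle_unit: week
  horizon_years: 10
  annual_discount_rate: 0.05
  wtp_threshold: 22200.0        # 3x Chinese per-capita GDP, USD per QALY
  currency_year: 2015

survival:
  control_pfs: {scale: 0.04191, shape: 1.4165}     # weekly Weibull, fitted to trial KM
  control_os: {scale: 0.02143, shape: 1.18716}
  hr_pfs: {hr: 0.34, ci_low: 0.27, ci_high: 0.595}  # apatinib vs control, pooled
  hr_os: {hr: 0.57, ci_low: 0.537, ci_high: 0.937}

costs:
  # Printed local charge for apatinib. price_basis "per_day" reads it as the
  # charge for the full 850 mg daily dose (the reading consistent with the
  # published base-case totals); "per_unit" reads it per 425 mg unit.
  apatinib_unit_cost: {value: 106.5, low: 53.2, high: 106.5}
  price_basis: per_day
  daily_dose_mg: 850.0
  unit_strength_mg: 425.0
  supportive_care_per_cycle: {value: 117.1, low: 32.3, high: 322.6}
  end_of_life_palliative: {value: 1483.9, low: 1072.3, high: 2119.3}
  coverage_fraction: {value: 0.60, low: 0.45, high: 0.75}   # range = +/-25% of base
  pfs_supportive_with_drug: false

utilities:
  u_pfs: {value: 0.88, low: 0.80, high: 0.97}   # time trade-off, progression-free
  u_pd: {value: 0.41, low: 0.28, high: 0.63}    # progressed disease

pap:
  enabled: true
  variant: "3+X"      # patients pay the first 3 months of drug, free thereafter
  paid_months: 3

budget:
  population: 1000000
  annual_incident_gc_per_million: 215.5   # ~21.55 per 100,000
  fraction_advanced: 0.6667               # about two-thirds present advanced
  fraction_reaching_third_line: 0.7
  uptake_by_year: [0.8, 1.0, 1.0, 1.0, 1.0]
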