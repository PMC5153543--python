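# Demo run: both trial-arm presets at reduced size, fixture drug prices,
# a small illustrative overhead ledger and capital register.
seed: 42
arms:
  - preset: chap
    config:
      n_patients: 60
    wages:
      physician: {monthly_wage: 640.0, monthly_hours: 160.0}
      nurse: {monthly_wage: 640.0, monthly_hours: 160.0}
  - preset: chapas
    config:
      n_patients: 60
    wages:
      physician: {monthly_wage: 1600.0, monthly_hours: 160.0}
      nurse: {monthly_wage: 640.0, monthly_hours: 160.0}
price_tables: ["bundled:all"]
overhead:
  ledger:
    administration: 120000.0
    security: 40000.0
    laundry: 25000.0
    catering: 60000.0
    utilities: 55000.0
  weights:
    administration: 0.25
    security: 0.25
    laundry: 0.18
    catering: 0.18
    utilities: 0.25
  bed_days: 36500.0
capital:
  assets:
    - {asset_name: paediatric block, replacement_cost: 1200000.0, useful_life: 40, category: building}
    - {asset_name: trial vehicle, replacement_cost: 30000.0, useful_life: 5, category: vehicle}
    - {asset_name: CD4 counter, replacement_cost: 80000.0, useful_life: 5, category: lab_equipment}
  discount_rate: 0.03
  allocation_weight: 0.1
  horizon_weeks: 96.0
lab:
  pricing: flat_panel
  flat_rate: 15.0
bootstrap:
  n_resamples: 2000
  level: 0.95
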