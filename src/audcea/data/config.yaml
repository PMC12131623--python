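# Default model configuration. Table paths are relative to this file.
model:
  horizon_years: 5.0
  short_cycle_years: 0.25
  short_phase_years: 1.0
  long_cycle_years: 1.0
  discount_rate: 0.03
  relapse_probability: 0.14
  cohort_size: 250
  psa_iterations: 1000
  grams_per_drink: 12.0
  seed: 0

tables:
  thresholds: drl_thresholds.csv
  mortality: synthetic_mortality.csv
  risks: synthetic_event_risks.csv
  utilities_drl: utilities_drl.csv
  utilities_events: utilities_events.csv
  event_costs: event_costs.csv
  transitions: synthetic_transitions_short_term.csv
  baseline_distribution: synthetic_baseline_distribution.csv
  utilities_drl_alt: synthetic_utilities_drl_alt.csv

arms:
  BSCT:
    female_proportion: 0.42
    baseline_age: 52.2
    intervention_costs:
      variable: 1446.01   # total 1447.79 minus the supervision/coding component
      supervision: 1.78
  MET:
    female_proportion: 0.54
    baseline_age: 51.4
    intervention_costs:
      variable: 1509.69   # total 1511.37 minus the supervision/coding component
      supervision: 1.68

scenarios:
  - name: discount_0pct
    overrides: {discount_rate: 0.0}
  - name: discount_5pct
    overrides: {discount_rate: 0.05}
  - name: no_supervision_costs
    overrides: {drop_supervision_costs: true}
  - name: relapse_19pct
    overrides: {relapse_probability: 0.19}
  - name: alternative_utilities
    overrides: {utilities_drl_table: synthetic_utilities_drl_alt.csv}
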