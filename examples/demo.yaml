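# Demo run: synthetic two-year cohort with encounter-data-like missingness,
# scored under the recommended hierarchical method and three alternatives.
seed: 42
output_dir: demo_out
cohort:
  n_patients: 150
  n_years: 3
  start_year: 2020
  churn: 0.2
  concentration: 0.6
missingness: ma_like
duplicate_rate: 0.05
methods:
  - encounter_scope: MEDICAL
    clinician_scope: PCP_THEN_ALL
    lookback: true
  - encounter_scope: MEDICAL
    clinician_scope: ALL_MD_APP
    lookback: false
  - encounter_scope: EM
    clinician_scope: PCP_ONLY
    lookback: false
  - encounter_scope: MEDICAL
    clinician_scope: PCP_THEN_ALL
    lookback: true
    level: TIN
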