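# Demo configuration: a small synthetic ED population that runs the
# whole pipeline in minutes on one CPU.
run:
  study_window: ["2016-06-01", "2022-06-01"]
  age_bands: [[6, 11], [12, 18]]
  top_k: 20
  min_patient_support: 20
  alpha: 0.05
  rng_seed: 0
  yates: true
  rank_by: p_cond
  comparator_index: last
  l2: 0.0001
  match_k: 1

generator:
  n_patients: 5000
  latent_prevalence: 0.07
  coding_sensitivity: 0.534
  child_fraction: 0.519
  extra_encounter_rate: 0.52
  female_multiplier: 2.0
  adolescent_multiplier: 4.0
  rng_seed: 0
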