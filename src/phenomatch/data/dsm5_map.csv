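code_or_prefix,category
# Representative ICD-10-CM -> DSM-5 category prefix map used to pool rare
# codes into disorder families.  Longest matching prefix wins; codes with
# no match are "unmapped".  Replace via the dsm5_map_path config key.
F0*,neurocognitive_disorders
F1*,substance_related_disorders
F2*,schizophrenia_spectrum_disorders
F30*,bipolar_disorder
F31*,bipolar_disorder
F32*,depressive_disorders
F33*,depressive_disorders
F34*,depressive_disorders
F39*,depressive_disorders
F40*,anxiety_disorders
F41*,anxiety_disorders
F42*,obsessive_compulsive_disorders
F43*,trauma_stressor_disorders
F44*,dissociative_disorders
F45*,somatic_symptom_disorders
F48*,other_mental_disorders
F50*,feeding_eating_disorders
F60*,personality_disorders
F63*,disruptive_impulse_conduct_disorders
F64*,gender_dysphoria
F7*,intellectual_disabilities
F80*,communication_disorders
F81*,specific_learning_disorder
F82*,motor_disorders
F84*,autism_spectrum_disorder
F88*,other_neurodevelopmental_disorders
F89*,other_neurodevelopmental_disorders
F90*,attention_deficit_hyperactivity_disorder
F91*,disruptive_impulse_conduct_disorders
F93*,anxiety_disorders
F94*,trauma_stressor_disorders
F95*,tic_disorders
F98*,elimination_disorders
F99*,other_mental_disorders
G21*,medication_induced_movement_disorders
G24*,medication_induced_movement_disorders
G47*,sleep_wake_disorders
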