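# Clinical severity catalog with mild/moderate/severe weighting (1/5/10 points).
# Item set transcribed from the complication summary of the study cohort; edit
# freely — the scoring contract is the grade->weight map and the cluster cutoff,
# not this particular item list.
name: ameratunga
cluster_cutoff: 14
default_grades: {mild: 1, moderate: 5, severe: 10}
items:
  - recurrent_infections
  - pneumonia
  - severe_infection
  - chronic_lung_disease
  - bronchiectasis
  - pulmonary_granulomata
  - glild
  - autoimmune_disease
  - granulomatous_infiltration
  - splenomegaly
  - splenectomy
  - enteropathy
  - malignancy
  - skin_musculoskeletal
  - endocrine_cardiac_renal_hepatic
  - allergy
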