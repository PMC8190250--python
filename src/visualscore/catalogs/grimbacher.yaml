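# 15-complication severity catalog; each item scores 0 (absent) to 3
# (confirmed/severe/surgical) points and the grade value is its own weight.
name: grimbacher
cluster_cutoff: 5
default_grades: {0: 0, 1: 1, 2: 2, 3: 3}
items:
  - autoimmunity
  - lymphoproliferation
  - enteropathy
  - malignancy
  - bronchiectasis
  - chronic_lung_disease
  - lung_surgery
  - splenectomy
  - splenomegaly
  - chronic_sinusitis
  - meningitis
  - encephalitis
  - pneumonia
  - severe_infections
  - granulomata
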