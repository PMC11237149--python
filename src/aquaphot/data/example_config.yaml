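# Headline synthetic experiment: plasma cohort (3 healthy, 2 CD, 8 UC subjects,
# 3 replicates each), healthy-vs-IBD classification over the full first-overtone
# window and the 12 WAMAC bands, leave-one-subject-out validation.
preset: plasma_ibd
label_scheme: 2class
ranges: [full_1300_1600, wamac12]
pretreatments:
  - steps: []                      # raw data
  - steps: [{name: snv}]
  - steps: [{name: snv}, {name: msc}]
models: [LDA, QDA, SVM]
validations: [loo]
loo_unit: subject
pc_threshold: 99.0
seed: 17
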