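# Tiny smoke-test configuration: inherits every field from published_calibration
# except the overrides below.  Meant for fast end-to-end runs and examples.
inherits: published_calibration
name: smoke_small
n_patients: 50
notes_per_patient:
  shift: 1
  mean: 6.0
  dispersion: 1.0
note_count_coupling:
  enabled: false
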