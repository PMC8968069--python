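# Demo session: jittered auditory-name paradigm, 20 channels, 5 responsive.
seed: 7
paradigm:
  n_trials: 60
  stim_duration_ms: 1000
  iti_ms: [1100, 1300]
  cue_ms: 100
  prep_ms: 500
  fs: 1000
session:
  n_channels: 20
  gain: 3.0
  line_amp: 5.0
window:
  window_len_ms: 400
  step_ms: 50
feature_set: four_type
classifier: hmm
n_perm:
  channels: 200
  features: 100
  chance: 0
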