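# Demo: 200 cells, 8 Hz stimulation, 30% of cells reverberate poststim.
generator:
  n_cells: 200
  background_rate: 0.5       # Hz per cell, homogeneous Poisson
  test_pulse_rate: 0.4       # Hz, slow viability pulses in both test epochs
  test1_duration: 20.0
  prestim_duration: 60.0
  poststim_duration: 60.0
  test2_duration: 20.0
  reverb_fraction: 0.3       # fraction of cells replaying the pattern
  reverb_duration: 20.0
  reverb_jitter_sd: 0.0      # s, Gaussian timing jitter on replayed spikes
  stim_response_prob: 1.0
  ei_fraction: 0.8

pattern:
  kind: single               # or: doublet (+ doublet_isi, pattern_period)
  frequency: 8.0             # Hz
  duration: 10.0

spikes:
  use_calcium: false         # true: render fluorescence and re-infer spikes
  decay_tau: 0.5
  threshold_sd: 4.0
  rise_time_threshold: 1.0

engramnet:
  enabled: true
  null_kind: mixed           # isi_shuffle | uniform_noise | prestim_slices | mixed
  window_cycles: 2
  window_step: 0.05
  threshold: 0.5
  classifier:
    hidden: 64
    max_epochs: 100

exposure: 0.02               # s per frame (20 ms)
seed: 1
outdir: runs/demo
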