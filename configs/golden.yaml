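# Packaged synthetic reference run: every stage, fixed seed.
seed: 17
n_sims: 2000
n_control_peaks: 32
generator:
  n_peaks: 1500
  n_gain_peaks: 80
  n_clustered_pairs: 40
analysis:
  fold_threshold: 2.0
  min_length: 500
  fdr_alpha: 0.05
  pseudo_density: 0.1
motif:
  name: GATA-1
  pattern: WGATTAG
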