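# Synthetic emulation of an AP lesion at a highly extrahelical site
seed: 1
report_decimals: 1
analyses: [extrahelicity, ejection, contacts]
synthetic:
  sequence: GCGCATATATGCGCG
  lesion: {position: 7, type: AP}
  orphan: {position: 8}
  n_frames: 1000
  noise_sigma: 0.1
  replicates:
    MD1: {mode: exact_fraction, fraction: 0.670}
    MD2: {mode: exact_fraction, fraction: 0.996}
    MD3: {mode: exact_fraction, fraction: 0.979}
  contact_script:
    episodes: [[0, 199, 4.0]]
    off_distance: 20.0
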