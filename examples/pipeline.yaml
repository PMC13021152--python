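# Full simulation pipeline: 10 samples on a 2x2 window at intensity 250,
# holes and tissue at module defaults, five tight high-abundance phenotype
# clusters, Gaussian marker values, simple-dialect CSV export.
seed: 42
core:
  n_sims: 10
  n_cell_types: 1
  lambda: 250
  window: {xmin: -1, xmax: 1, ymin: -1, ymax: 1}
tissue:
  k: 2
  sdmin: 0.5
  sdmax: 1.0
  prob_min: 0.2
  prob_max: 0.8
holes:
  k: 1
  sdmin: 0.2
  sdmax: 0.4
  prob_min: 0.1
  prob_max: 0.3
  drop: false
cells:
  k: 5
  sdmin: 0.1
  sdmax: 0.3
  prob_min: 0.01
  prob_max: 0.75
  shift: 0.0
distributions:
  mean_pos: 10
  sd_pos: 1
  mean_neg: 5
  sd_neg: 1
export:
  dialect: simple
  drop_holes: false
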