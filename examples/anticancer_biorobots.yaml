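# Showcase: anticancer_biorobots (built programmatically; domain/substrates are set by
# the builder, this file selects the model and seed).
sample_model: anticancer_biorobots
seed: 1
domain: {x_min: -300, x_max: 300, y_min: -300, y_max: 300, z_min: -300, z_max: 300, dx: 20}
substrates:
  - {name: oxygen, units: mmHg, D: 2.0e+3, lambda: 0.01, initial: 38.0,
     boundary: {type: dirichlet, value: 38.0}}
output: {dir: output/anticancer_biorobots}
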