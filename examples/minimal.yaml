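# Minimal non-showcase run: three live-model tumor cells consuming oxygen.
seed: 7
domain: {x_min: 0, x_max: 200, y_min: 0, y_max: 200, z_min: 0, z_max: 200, dx: 20}
time: {dt_diff: 0.01, dt_mech: 0.1, dt_cells: 6.0, dt_save: 30.0, t_max: 60.0}
substrates:
  - {name: oxygen, units: mmHg, D: 1.0e+5, lambda: 0.01, initial: 38.0,
     boundary: {type: dirichlet, value: 38.0}}
cell_types:
  - name: tumor
    cycle: {model: live, birth_rate: 0.001}
    secretion: {oxygen: {U: 10.0}}
placements:
  - {type: spheroid, cell_type: tumor, n: 20, center: [100, 100, 100], spacing: 16}
output: {dir: output/minimal}
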