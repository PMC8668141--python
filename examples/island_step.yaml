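# Abrupt environmental change on the island: stationary start at weak
# migration / low carrying capacity, step to strong migration / K = 50.
# Run:  dmaxent compare step --config examples/island_step.yaml
model: island
protocol:
  kind: step
  levels:
    - [0.05, 0.005, 1.0]   # r, lambda, m  (K = 10)
    - [0.10, 0.002, 3.0]   # K = 50
initial: [0.05, 0.005, 1.0]
horizon: 40.0
n_out: 81
dt: 0.01
n_traj: 3000
seed: 0
fpe_cells: 400
snapshot_times: [1, 5, 10, 40]
methods: [dme, fpe, ensemble, matrix]
outdir: out_island_step
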