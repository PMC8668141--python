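# Periodic shifts of the carrying capacity between 20 and 50 after a
# stationary start at (0.05, 0.005, 1).  Switch kind to square_wave (or
# ramp_fraction) to compare abrupt vs smooth drives.
# Run:  dmaxent compare periodic --config examples/island_periodic.yaml
model: island
protocol:
  kind: smooth_periodic
  levels:
    - [0.1, 0.005, 3.0]    # K = 20
    - [0.1, 0.002, 3.0]    # K = 50
  period: 20.0
  ramp_fraction: 1.0
initial: [0.05, 0.005, 1.0]
horizon: 60.0
n_out: 301
fpe_cells: 400
methods: [dme, fpe]
outdir: out_island_periodic
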