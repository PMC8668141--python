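# Alternative periodic configuration with an order-of-magnitude weaker
# density regulation (carrying capacities 200 and 500).  Heavier than the
# default: populations are larger and the density grid must reach further.
model: island
protocol:
  kind: square_wave
  levels:
    - [0.1, 0.0005, 3.0]   # K = 200
    - [0.1, 0.0002, 3.0]   # K = 500
  period: 20.0
initial: [0.05, 0.005, 1.0]
horizon: 60.0
n_out: 301
fpe_cells: 800
methods: [dme, fpe]
outdir: out_island_periodic_lowreg
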