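# OU step change: stationary start at (mu, beta) = (0.1, 0.45), relaxation
# towards (1, 0.7) with sigma0 = 0.1.  The reduction is exact here.
# Run:  dmaxent compare step --config examples/ou_step.yaml
model: ou
sigma0: 0.1
protocol:
  kind: step
  levels:
    - [0.1, 0.45]   # mu, beta
    - [1.0, 0.70]
initial: [0.1, 0.45]
horizon: 10.0
n_out: 101
fpe_cells: 1500
snapshot_times: [0.3, 1, 2, 5]
methods: [dme, fpe]
outdir: out_ou_step
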