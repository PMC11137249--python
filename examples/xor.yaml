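# Noisy-XOR small-task configuration (published small-dataset parameters)
task: xor
n: 1000
n_test: 100
hidden_dims: [10, 4]
kind: rate
dt: 1.0          # ms
dt_sample: 20.0  # ms per sample
N: 64            # working-memory capacity (effective batch size)
gamma: 10.0
sigma_x: 0.3
sigma_z: 2.0
sigma_y: 0.25
eta: 1.0e-4
epochs: 25
optimizer: adam
xi_source: oracle
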