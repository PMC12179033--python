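# dominance-game scenario with strong conflict (cf. the fig1-right preset)
game: {alpha: -1, beta: -1, gamma: 1.5, P: 1}
kernel: {family: fermi, s: 1.0}
lambda: 14
dt: 0.003
n_steps: 1400
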