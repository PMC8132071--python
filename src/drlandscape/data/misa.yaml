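# Two-gene mutual-inhibition self-activation switch: kinetic parameters
# and the frozen calibrated diffusion coefficient.
S: 0.5
n: 4
k: 1.0
g0: 0.0
a: 0.5
b: 0.5
d: 0.02
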