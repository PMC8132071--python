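# Synthetic 4-node self-activation / mutual-inhibition network.
# Frozen parameters give exactly 7 stable states.
S: 0.5
n: 4
k: 1.0
g0: 0.0
d: 0.02
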