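source	target	sign	strength
gene1	gene1	activate	0.5
gene2	gene2	activate	0.5
gene1	gene2	inhibit	0.5
gene2	gene1	inhibit	0.5
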