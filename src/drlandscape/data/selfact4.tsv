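source	target	sign	strength
gene1	gene1	activate	0.5
gene2	gene2	activate	0.51
gene3	gene3	activate	0.52
gene4	gene4	activate	0.53
gene1	gene2	inhibit	0.22
gene1	gene3	inhibit	0.22
gene1	gene4	inhibit	0.22
gene2	gene1	inhibit	0.22
gene2	gene3	inhibit	0.22
gene2	gene4	inhibit	0.22
gene3	gene1	inhibit	0.22
gene3	gene2	inhibit	0.22
gene3	gene4	inhibit	0.22
gene4	gene1	inhibit	0.22
gene4	gene2	inhibit	0.22
gene4	gene3	inhibit	0.22
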