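species	n_genotypes
Setaria faberi	12
Setaria italica	10
Setaria viridis	192
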