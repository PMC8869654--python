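symbol	description	ratio_cortex_6m	ratio_glomeruli_2m	ratio_glomeruli_4m
NUDT19	Nucleoside diphosphate-linked moiety X	0.236	0.25	0.23
PIPOX	Peroxisomal sarcosine oxidase	0.406	0.567	0.615
AMACR	Alpha-methylacyl-CoA racemase	0.185	0.52	0.56
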