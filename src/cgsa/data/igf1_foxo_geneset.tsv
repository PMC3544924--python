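# Gene-set membership: the pig IGF1/FoxO signalling pathway.
set	gene_id
IGF1-FoxO	IGF1
IGF1-FoxO	IGFBP1
IGF1-FoxO	IGFBP2
IGF1-FoxO	IGFBP3
IGF1-FoxO	IGFBP4
IGF1-FoxO	IGFBP5
IGF1-FoxO	IGFBP6
IGF1-FoxO	INSR
IGF1-FoxO	IRS1
IGF1-FoxO	IRS4
IGF1-FoxO	PIK3R1
IGF1-FoxO	PIK3R2
IGF1-FoxO	PIK3R3
IGF1-FoxO	PDK1
IGF1-FoxO	PDK2
IGF1-FoxO	PDK3
IGF1-FoxO	PDK4
IGF1-FoxO	AKT1
IGF1-FoxO	AKT2
IGF1-FoxO	AKT3
IGF1-FoxO	FOXO1
IGF1-FoxO	FOXO3
IGF1-FoxO	FOXO4
IGF1-FoxO	FOXO6
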