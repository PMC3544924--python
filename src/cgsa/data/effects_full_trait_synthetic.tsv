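# Synthetic default QTN effect table for the full (a+d+epistasis) trait design.
# 13 QTNs on the default 57-SNP panel; additive ~ N(0,1), dominance ~ N(0,0.5), drawn once and frozen.
snp_id	additive	dominance
snp3	0.669941	0.843252
snp5	0.901073	0.453424
snp11	-1.555039	-0.876252
snp14	-1.326430	-1.245368
snp17	-0.611098	-0.144965
snp21	-0.440423	0.055087
snp24	1.177721	0.438768
snp28	0.108203	0.541957
snp30	0.962829	-0.173352
snp37	-1.194446	-0.542410
snp42	-0.506503	0.874470
snp49	0.377330	-0.307784
snp55	1.569408	-0.000066
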