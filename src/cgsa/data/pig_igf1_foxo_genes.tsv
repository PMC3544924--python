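# Pig ortholog coordinates of the IGF1/FoxO signalling-pathway genes
# (Sus scrofa build 9.2; 1-based inclusive base pairs; chrom labels are strings, "X" included).
gene_id	chrom	start	end
IGF1	5	77082628	77154428
IGFBP1	18	48650114	48654870
IGFBP2	15	112022157	112022652
IGFBP3	18	48778107	48782267
IGFBP4	12	19797073	19811336
IGFBP5	15	112017411	112019845
IGFBP6	5	16854964	16855290
INSR	2	50637472	50720384
IRS1	15	120872701	120981690
IRS4	X	88228629	88230746
PIK3R1	16	44114529	44120792
PIK3R2	2	62387523	62399642
PIK3R3	6	118327752	118488382
PDK1	15	73606993	73615575
PDK2	12	24797209	24801353
PDK3	X	19401655	19471675
PDK4	9	70465829	70477355
AKT1	6	38477164	38484612
AKT2	6	33533100	33560034
AKT3	10	16162075	16280499
FOXO1	11	15075341	15085340
FOXO3	1	78223324	78349962
FOXO4	X	56862227	56867783
FOXO6	11	15207819	15208487
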