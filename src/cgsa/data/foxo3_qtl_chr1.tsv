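# Pig QTLdb confidence intervals co-localizing with FOXO3.
# The source catalogue extract has no chromosome column; all records lie on
# chromosome 1 (FOXO3's chromosome), recorded here explicitly.
QTL_ID	QTL_symbol	Trait_name	QTL_start	QTL_end	chrom
3793	BFT	Average backfat thickness	52423837	166525431	1
5670	BFT	Average backfat thickness	3320998	144078329	1
5680	ADG	Average daily gain (10 weeks-slaughter)	3320998	193909568	1
329	ADG	Average daily gain (25-90 kg)	32980500	109360545	1
5928	ADG	Average daily gain (on weaning)	52423837	86769928	1
45	LUMBF	Backfat at last lumbar	73990528	154961837	1
3794	LRIBF	backfat at last rib	52423837	166525431	1
5674	LRIBF	backfat at last rib	7302766	163511869	1
651	BFTR	Backfat at rump	43291013	144078329	1
3795	10RIBBFT	Backfat at tenth rib7	52423837	158592899	1
5672	10RIBBFT	Backfat at tenth rib	26500027	86769928	1
5679	BYLEAN	Belly meat content	7302766	163511869	1
2845	BELLYWT	Belly weight	51386391	139615854	1
5931	WWT	Body weight (weaning)	52423837	86769928	1
4260	CD2L	CD2-positive leukocyte number	24598042	144803085	1
4261	CD4L	CD4-positive leukocyte number	24598042	144803085	1
5669	cond	Conductivity 24 hours postmortem (ham)	52423837	166525431	1
5668	cond	Conductivity 24 hours postmortem (loin)	52423837	118433791	1
6366	CREAT	Creatinine level	33269805	126505160	1
8885	EAREA	Ear area	43291013	109360545	1
8886	EAREA	Ear area	43291013	109360545	1
8853	EARWT	Ear weight	43291013	109360545	1
8854	EARWT	Ear weight	43291013	109360545	1
5678	ECLC	Estimated carcass lean content	7302766	163511869	1
5676	FATAREA	Fat area	11402561	144078329	1
5677	FP	Fat ratio (percentage)	7302766	163511869	1
871	FEEDIN	Feed Intake	26957266	91781628	1
8908	FSCOREF	feet score (front)	32980500	108464751	1
860	HEADWT	Head weight	26957266	91781628	1
5420	HCT	hematocrit	33269805	126505160	1
8910	LSCOREH	leg score (hind)	32980500	108464751	1
872	LIVWT	Liver weight	26957266	91781628	1
3796	LMA	Loin muscle area	52423837	158592899	1
5468	LYMPH	Lymphocyte number	33269805	126505160	1
2930	MARB	Marbling	52423837	91781628	1
4019	MARB	Marbling	27710381	179573387	1
78	MARB	Marbling	73990528	86769928	1
5667	COLORO	Meat color OPTO QTL	52423837	163511869	1
5664	pH	pH for Longissmus Dorsi	52423837	118433791	1
5666	pH	pH for Longissmus Dorsi	52423837	118433791	1
5665	pH	pH for Semimembranosus	52423837	118433791	1
6380	BPOTASS	Potassium level	33269805	126505160	1
9658	PRRSVAB	PRRSV antibody titer	26500027	144251236	1
5675	SIDEF	Side fat	26500027	86769928	1
5671	SHOUFATD	Subcutaneous fat depth at shoulder	3320998	163511869	1
6481	TNUM	Teat number	43291013	109360545	1
79	TOTLIP	Total lipid	24598042	129115585	1
611	WBC	White blood cell counts	32980500	108464751	1
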