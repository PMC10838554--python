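# genome_id: MT457820
# genome_length: 17827
# circular: true
# source: published annotation of the Pterorhinus chinensis complete mitogenome (GenBank MT457820)
# note: length and intergenic columns are the values as printed in the source record's
# note: annotation table; mitocharacter always recomputes both from coordinates and
# note: reports discrepancies rather than trusting them.
gene	strand	start	stop	length	intergenic	anticodon	start_codon	stop_codon
trnF	H	1	70	70	-1	GAA
12S	H	70	1056	987	-1
trnV	H	1056	1125	70	7	TAC
16S	H	1133	2722	1590	1
trnL2	H	2724	2798	75	14	TAA
nad1	H	2813	3790	978	8		ATG	TAA
trnI	H	3799	3872	74	5	GAT
trnQ	L	3878	3948	71	1	TTG
trnM	H	3948	4016	69	0	CAT
nad2	H	4017	5057	1041	-1		ATG	TAA
trnW	H	5057	5127	71	1	TCA
trnA	L	5129	5197	69	10	TGC
trnN	L	5208	5280	73	1	GTT
trnC	L	5282	5347	66	-1	GCA
trnY	L	5347	5417	71	1	GTA
cox1	H	5419	6969	1551	-9		ATG	AGG
trnS2	L	6961	7033	73	4	TGA
trnD	H	7038	7106	69	10	GTC
cox2	H	7117	7800	684	0		ATG	TAA
trnK	H	7801	7870	70	1	TTT
atp8	H	7872	8039	168	-10		ATG	TAA
atp6	H	8030	8713	684	5		ATG	TAA
cox3	H	8719	9502	784	0		ATG	T(AA)
trnG	H	9503	9571	69	0	TCC
nad3	H	9572	9922	351	-1		ATG	TAA
trnR	H	9922	9991	70	1	TCG
nad4l	H	9993	10289	297	-7		ATG	TAA
nad4	H	10283	11660	1378	0		ATG	T(AA)
trnH	H	11661	11730	70	0	GTG
trnS1	H	11731	11796	66	-1	GCT
trnL1	H	11796	11866	71	0	TAG
nad5	H	11867	13684	1818	8		ATG	AGA
cob	H	13693	14835	1143	3		ATG	TAA
trnT	H	14839	14907	69	311	TGT
CR1	H	15219	15882	664	126
trnP	L	16009	16077	69	6	TGG
nad6	L	16084	16602	519	1		ATG	TAG
trnE	L	16604	16675	72	297	TTC
CR2	H	16973	17651	679	175
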