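# source: published codon counts and RSCU values for the Pterorhinus chinensis
# source: mitogenome (GenBank MT457820); counts total 5942 = floor(17827/3).
# note: family column is the one-letter amino acid under the standard genetic code
# note: (the synonymous-family grouping the printed RSCU values obey); '*' = stop.
codon	family	count	rscu
UUU	F	56	0.53
UUC	F	154	1.47
UUA	L	72	0.69
UUG	L	31	0.30
CUU	L	126	1.21
CUC	L	149	1.43
CUA	L	181	1.74
CUG	L	65	0.63
AUU	I	103	0.86
AUC	I	156	1.30
AUA	I	102	0.85
AUG	M	74	1.00
GUU	V	47	0.98
GUC	V	53	1.11
GUA	V	63	1.32
GUG	V	28	0.59
UCU	S	93	1.08
UCC	S	123	1.42
UCA	S	93	1.08
UCG	S	31	0.36
CCU	P	281	1.57
CCC	P	209	1.17
CCA	P	173	0.97
CCG	P	52	0.29
ACU	T	172	1.43
ACC	T	143	1.19
ACA	T	136	1.13
ACG	T	30	0.25
GCU	A	62	0.90
GCC	A	102	1.48
GCA	A	87	1.27
GCG	A	24	0.35
UAU	Y	61	0.69
UAC	Y	116	1.31
UAA	*	87	1.21
UAG	*	51	0.71
CAU	H	167	0.96
CAC	H	181	1.04
CAA	Q	173	1.42
CAG	Q	71	0.58
AAU	N	141	0.81
AAC	N	208	1.19
AAA	K	158	1.33
AAG	K	80	0.67
GAU	D	46	0.73
GAC	D	80	1.27
GAA	E	76	1.31
GAG	E	40	0.69
UGU	C	28	0.61
UGC	C	64	1.39
UGA	*	78	1.08
UGG	W	30	1.00
CGU	R	44	0.74
CGC	R	71	1.20
CGA	R	57	0.96
CGG	R	39	0.66
AGU	S	53	0.61
AGC	S	126	1.46
AGA	R	80	1.35
AGG	R	64	1.08
GGU	G	38	0.76
GGC	G	64	1.27
GGA	G	72	1.43
GGG	G	27	0.54
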