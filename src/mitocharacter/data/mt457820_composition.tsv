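# source: published composition and skew table for the Pterorhinus chinensis
# source: complete mitogenome (GenBank MT457820); all cells as printed.
region	size	A	C	T	G	at_content	gc_content	at_skew	gc_skew
mtDNA	17827	29.45	32.81	23.26	14.48	52.71	47.29	0.12	-0.39
PCGs	11369	27.47	33.73	24.13	14.67	51.60	48.40	0.06	-0.39
tRNAs	1546	28.96	20.71	28.18	22.15	57.14	42.89	0.01	0.03
rRNAs	2577	33.18	25.89	20.36	20.57	53.54	46.46	0.24	-0.11
CRs	1343	20.86	31.55	30.27	17.32	51.13	48.87	-0.18	-0.29
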