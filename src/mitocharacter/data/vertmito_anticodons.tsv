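# Canonical vertebrate mitochondrial tRNA anticodons (DNA alphabet, 5'->3').
trna	anticodon
trnF	GAA
trnV	TAC
trnL2	TAA
trnI	GAT
trnQ	TTG
trnM	CAT
trnW	TCA
trnA	TGC
trnN	GTT
trnC	GCA
trnY	GTA
trnS2	TGA
trnD	GTC
trnK	TTT
trnG	TCC
trnR	TCG
trnH	GTG
trnS1	GCT
trnL1	TAG
trnT	TGT
trnP	TGG
trnE	TTC
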