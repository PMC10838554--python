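# version: 1
# Normalization map from common GenBank gene/product spellings to the canonical
# lower-case names used throughout mitocharacter. Matching is case-insensitive
# and ignores spaces/hyphens/underscores. Leu/Ser tRNAs that cannot be
# disambiguated from the name alone are resolved by anticodon where available.
alias	canonical
nd1	nad1
nd2	nad2
nd3	nad3
nd4	nad4
nd4l	nad4l
nd5	nad5
nd6	nad6
nadh1	nad1
nadh2	nad2
nadh3	nad3
nadh4	nad4
nadh4l	nad4l
nadh5	nad5
nadh6	nad6
nadhdehydrogenasesubunit1	nad1
nadhdehydrogenasesubunit2	nad2
nadhdehydrogenasesubunit3	nad3
nadhdehydrogenasesubunit4	nad4
nadhdehydrogenasesubunit4l	nad4l
nadhdehydrogenasesubunit5	nad5
nadhdehydrogenasesubunit6	nad6
cox1	cox1
cox2	cox2
cox3	cox3
coxi	cox1
coxii	cox2
coxiii	cox3
co1	cox1
co2	cox2
co3	cox3
coi	cox1
coii	cox2
coiii	cox3
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunitiii	cox3
cytochromecoxidasesubunit1	cox1
cytochromecoxidasesubunit2	cox2
cytochromecoxidasesubunit3	cox3
cytb	cob
cob	cob
cytochromeb	cob
atp6	atp6
atp8	atp8
atpase6	atp6
atpase8	atp8
atpsynthasef0subunit6	atp6
atpsynthasef0subunit8	atp8
12srrna	12S
12sribosomalrna	12S
srrna	12S
rrns	12S
rrn12	12S
smallsubunitribosomalrna	12S
16srrna	16S
16sribosomalrna	16S
lrrna	16S
rrnl	16S
rrn16	16S
largesubunitribosomalrna	16S
dloop	CR
controlregion	CR
cr	CR
trnf	trnF
trnv	trnV
trni	trnI
trnq	trnQ
trnm	trnM
trnw	trnW
trna	trnA
trnn	trnN
trnc	trnC
trny	trnY
trnd	trnD
trnk	trnK
trng	trnG
trnr	trnR
trnh	trnH
trnt	trnT
trnp	trnP
trne	trnE
trnl1	trnL1
trnl2	trnL2
trns1	trnS1
trns2	trnS2
trnaphe	trnF
trnaval	trnV
trnaile	trnI
trnagln	trnQ
trnamet	trnM
trnatrp	trnW
trnaala	trnA
trnaasn	trnN
trnacys	trnC
trnatyr	trnY
trnaasp	trnD
trnalys	trnK
trnagly	trnG
trnaarg	trnR
trnahis	trnH
trnathr	trnT
trnapro	trnP
trnaglu	trnE
trnaleu	trnL
trnaser	trnS
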