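synonym	canonical
COX1	cox1
COX2	cox2
COX3	cox3
COXI	cox1
COXII	cox2
COXIII	cox3
COI	cox1
COII	cox2
COIII	cox3
CO1	cox1
CO2	cox2
CO3	cox3
MTCO1	cox1
MTCO2	cox2
MTCO3	cox3
CYTOCHROMECOXIDASESUBUNIT1	cox1
CYTOCHROMECOXIDASESUBUNIT2	cox2
CYTOCHROMECOXIDASESUBUNIT3	cox3
CYTOCHROMECOXIDASESUBUNITI	cox1
CYTOCHROMECOXIDASESUBUNITII	cox2
CYTOCHROMECOXIDASESUBUNITIII	cox3
ND1	nad1
ND2	nad2
ND3	nad3
ND4	nad4
ND4L	nad4L
ND5	nad5
ND6	nad6
NAD1	nad1
NAD2	nad2
NAD3	nad3
NAD4	nad4
NAD4L	nad4L
NAD5	nad5
NAD6	nad6
NADH1	nad1
NADH2	nad2
NADH3	nad3
NADH4	nad4
NADH4L	nad4L
NADH5	nad5
NADH6	nad6
NADHDEHYDROGENASESUBUNIT1	nad1
NADHDEHYDROGENASESUBUNIT2	nad2
NADHDEHYDROGENASESUBUNIT3	nad3
NADHDEHYDROGENASESUBUNIT4	nad4
NADHDEHYDROGENASESUBUNIT4L	nad4L
NADHDEHYDROGENASESUBUNIT5	nad5
NADHDEHYDROGENASESUBUNIT6	nad6
ATP6	atp6
ATP8	atp8
ATPASE6	atp6
ATPASE8	atp8
ATPSYNTHASEF0SUBUNIT6	atp6
ATPSYNTHASEF0SUBUNIT8	atp8
CYTB	cytb
CYB	cytb
COB	cytb
CYTOCHROMEB	cytb
12S	rrnS
12SRRNA	rrnS
12SRIBOSOMALRNA	rrnS
SRRNA	rrnS
RRNS	rrnS
SMALLSUBUNITRIBOSOMALRNA	rrnS
16S	rrnL
16SRRNA	rrnL
16SRIBOSOMALRNA	rrnL
LRRNA	rrnL
RRNL	rrnL
LARGESUBUNITRIBOSOMALRNA	rrnL
TRNA	trnA
TRNR	trnR
TRNN	trnN
TRND	trnD
TRNC	trnC
TRNQ	trnQ
TRNE	trnE
TRNG	trnG
TRNH	trnH
TRNI	trnI
TRNK	trnK
TRNM	trnM
TRNF	trnF
TRNP	trnP
TRNT	trnT
TRNW	trnW
TRNY	trnY
TRNV	trnV
TRNL1	trnL1
TRNL2	trnL2
TRNS1	trnS1
TRNS2	trnS2
TRNAALA	trnA
TRNAARG	trnR
TRNAASN	trnN
TRNAASP	trnD
TRNACYS	trnC
TRNAGLN	trnQ
TRNAGLU	trnE
TRNAGLY	trnG
TRNAHIS	trnH
TRNAILE	trnI
TRNALYS	trnK
TRNAMET	trnM
TRNAPHE	trnF
TRNAPRO	trnP
TRNATHR	trnT
TRNATRP	trnW
TRNATYR	trnY
TRNAVAL	trnV
TRNALEUCUN	trnL1
TRNALEUUUR	trnL2
TRNALEUTAG	trnL1
TRNALEUTAA	trnL2
TRNASERAGN	trnS1
TRNASERUCN	trnS2
TRNASERTCT	trnS1
TRNASERTGA	trnS2
TRNLCUN	trnL1
TRNLUUR	trnL2
TRNSAGN	trnS1
TRNSUCN	trnS2
CR	CR
DLOOP	CR
CONTROLREGION	CR
ATRICHREGION	CR
ATRICH	CR
PUTATIVECONTROLREGION	CR
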