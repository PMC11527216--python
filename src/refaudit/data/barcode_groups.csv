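canonical,synonym
CO1,CO1
CO1,COI
CO1,COX1
CO1,COXI
CO1,cytochrome c oxidase subunit I
CO1,cytochrome oxidase subunit 1
CO1,cytochrome c oxidase subunit 1
16S,16S
16S,16S rRNA
16S,16S ribosomal RNA
16S,rrnL
18S,18S
18S,18S rRNA
18S,18S ribosomal RNA
18S,small subunit ribosomal RNA
12S,12S
12S,12S rRNA
12S,12S ribosomal RNA
12S,Vert12S
12S,MT-RNR1
FITS,FITS
FITS,fungal ITS
FITS,fungal internal transcribed spacer
PITS,PITS
PITS,plant ITS
PITS,plant internal transcribed spacer
trnL,trnL
trnL,trnL-F
trnL,trnL (UAA)
trnL,trnL intron
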