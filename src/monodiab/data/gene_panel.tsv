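gene_symbol	modes
GCK	autosomal_dominant
HNF1A	autosomal_dominant
HNF4A	autosomal_dominant
HNF1B	autosomal_dominant
INS	autosomal_dominant,autosomal_recessive
ABCC8	autosomal_dominant,autosomal_recessive
KCNJ11	autosomal_dominant,autosomal_recessive
PDX1	autosomal_dominant,autosomal_recessive
NEUROD1	autosomal_dominant,autosomal_recessive
CEL	autosomal_dominant
KLF11	autosomal_dominant
PAX4	autosomal_dominant
BLK	autosomal_dominant
APPL1	autosomal_dominant
GATA4	autosomal_dominant
GATA6	autosomal_dominant
ZFP57	autosomal_recessive
STAT3	autosomal_dominant
INSR	autosomal_dominant,autosomal_recessive
AKT2	autosomal_dominant
WFS1	autosomal_dominant,autosomal_recessive
SLC19A2	autosomal_recessive
SLC29A3	autosomal_recessive
EIF2AK3	autosomal_recessive
IER3IP1	autosomal_recessive
NEUROG3	autosomal_recessive
PTF1A	autosomal_recessive
GLIS3	autosomal_recessive
SLC2A2	autosomal_recessive
TRMT10A	autosomal_recessive
DNAJC3	autosomal_recessive
CISD2	autosomal_recessive
PCBD1	autosomal_recessive
MNX1	autosomal_recessive
NKX2-2	autosomal_recessive
RFX6	autosomal_recessive
YIPF5	autosomal_recessive
EIF2B1	autosomal_dominant
ONECUT1	autosomal_recessive
PDIA6	autosomal_recessive
TBC1D4	autosomal_recessive
POLD1	autosomal_dominant
LRBA	autosomal_recessive
ITCH	autosomal_recessive
CTLA4	autosomal_dominant
FOXP3	x_linked
BSCL2	autosomal_recessive
AGPAT2	autosomal_recessive
PPARG	autosomal_dominant
MT-TL1	mitochondrial
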