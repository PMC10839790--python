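# Antigen processing and presentation gene set (KEGG pathway hsa04612, 78 genes).
gene
HLA-A
HLA-B
HLA-C
HLA-E
HLA-F
HLA-G
HLA-DRA
HLA-DRB1
HLA-DRB3
HLA-DRB4
HLA-DRB5
HLA-DQA1
HLA-DQA2
HLA-DQB1
HLA-DPA1
HLA-DPB1
HLA-DMA
HLA-DMB
HLA-DOA
HLA-DOB
B2M
TAP1
TAP2
TAPBP
PSMB8
PSMB9
PSME1
PSME2
PSME3
CALR
CANX
PDIA3
HSPA1A
HSPA1B
HSPA1L
HSPA2
HSPA4
HSPA5
HSPA6
HSPA8
HSP90AA1
HSP90AB1
CTSB
CTSL
CTSS
LGMN
IFI30
CD4
CD8A
CD8B
CD74
CIITA
CREB1
NFYA
NFYB
NFYC
RFX5
RFXANK
RFXAP
KIR2DL1
KIR2DL2
KIR2DL3
KIR2DL4
KIR2DL5A
KIR2DS1
KIR2DS2
KIR2DS3
KIR2DS4
KIR2DS5
KIR3DL1
KIR3DL2
KIR3DL3
KIR3DS1
KLRC1
KLRC2
KLRC3
KLRC4
KLRD1
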