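# Targeted genes for CNV/LOH analysis on chromosome arms 6p (HLA region),
# 15q (B2M) and 16p (CIITA).  Coordinates are 1-based inclusive, GRCh38.
gene	chromosome	start	end	role
HLA-A	6	29941260	29945884	HLA-classI
HLA-C	6	31268749	31272130	HLA-classI
HLA-B	6	31353875	31357188	HLA-classI
HLA-DRB1	6	32578775	32589848	HLA-classII
HLA-DQA1	6	32628179	32647062	HLA-classII
HLA-DQB1	6	32659467	32668383	HLA-classII
TAP2	6	32821755	32838739	APP
PSMB8	6	32840717	32844679	APP
TAP1	6	32845209	32853816	APP
PSMB9	6	32854192	32859851	APP
HLA-DPA1	6	33064569	33080775	HLA-classII
HLA-DPB1	6	33075990	33089696	HLA-classII
TAPBP	6	33299691	33314066	APP
B2M	15	44711477	44718877	B2M
CIITA	16	10866208	10943021	CIITA
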