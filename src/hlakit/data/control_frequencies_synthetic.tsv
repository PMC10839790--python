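# SYNTHETIC control allele-frequency fixture: a constructed stand-in, with
# plausible European-ancestry magnitudes, for the published control tables
# that users should supply for real screening.
locus	allele	frequency	source
A	01:01	0.14	synthetic-controls
A	02:01	0.27	synthetic-controls
A	03:01	0.13	synthetic-controls
A	11:01	0.06	synthetic-controls
A	24:02	0.09	synthetic-controls
B	07:02	0.14	synthetic-controls
B	08:01	0.12	synthetic-controls
B	18:01	0.05	synthetic-controls
B	44:02	0.09	synthetic-controls
C	07:01	0.15	synthetic-controls
C	07:02	0.15	synthetic-controls
C	12:03	0.05	synthetic-controls
DRB1	15:01	0.13	synthetic-controls
DRB1	03:01	0.11	synthetic-controls
DQB1	06:02	0.132	synthetic-controls
DQB1	02:01	0.11	synthetic-controls
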