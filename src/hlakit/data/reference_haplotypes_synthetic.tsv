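# SYNTHETIC A-B-C reference haplotype fixture: a constructed stand-in, with
# plausible European-ancestry haplotypes and magnitudes, for the registry
# tables users should supply for real assignment.
rank	A	B	C	frequency
1	A*01:01	B*08:01	C*07:01	0.070
2	A*03:01	B*07:02	C*07:02	0.050
3	A*02:01	B*44:02	C*05:01	0.040
4	A*02:01	B*07:02	C*07:02	0.030
5	A*29:02	B*44:03	C*16:01	0.020
6	A*02:01	B*15:01	C*03:04	0.020
7	A*24:02	B*35:01	C*04:01	0.020
8	A*01:01	B*57:01	C*06:02	0.020
9	A*11:01	B*35:01	C*04:01	0.015
10	A*32:01	B*14:02	C*08:02	0.010
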