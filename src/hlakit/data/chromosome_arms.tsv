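# Chromosome arm boundaries (1-based inclusive, GRCh38) for arm-level calls.
arm	chromosome	start	end
6p	6	1	59800000
15q	15	19700000	101991189
16p	16	1	36800000
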