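# Linkage between DRB1 allele groups (field1) and DR haplotype groups:
# DR1/DR8 haplotypes carry DRB1 alone, DR51 carries DRB5, DR52 carries DRB3,
# DR53 carries DRB4.  Editable; every DRB1 allele group in the input cohort
# must have an entry.
drb1_group	dr_group
1	DR1
10	DR1
8	DR8
15	DR51
16	DR51
3	DR52
11	DR52
12	DR52
13	DR52
14	DR52
4	DR53
7	DR53
9	DR53
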