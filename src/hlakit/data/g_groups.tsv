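# Small G-group fixture: alleles sharing identical exon sequence over the
# peptide-binding domains; a full IMGT/HLA import is out of scope and users
# may supply their own table with the same columns.
locus	allele	g_group
DQA1	03:01	DQA1*03:01:01G
DQA1	03:02	DQA1*03:01:01G
DQA1	03:03	DQA1*03:01:01G
DQA1	05:01	DQA1*05:01:01G
DQA1	05:05	DQA1*05:01:01G
DQA1	05:09	DQA1*05:01:01G
B	44:02	B*44:02:01G
B	44:27	B*44:02:01G
C	07:01	C*07:01:01G
C	07:06	C*07:01:01G
C	07:18	C*07:01:01G
DQB1	06:02	DQB1*06:02:01G
DQB1	06:46	DQB1*06:02:01G
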