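# Novel variants reported for the congenital myopathy / congenital muscular dystrophy
# cohort, transcribed verbatim. Two gene symbols are kept exactly as printed and
# annotated: "PIEZ02" (probable typo for PIEZO2) and "MMF" (symbol unresolved).
disease_category	gene_symbol	variant	acmg_class	annotation
CM/CMD	NEB	ENST00000397345.8:c.17502_17510dup	LP
CM/CMD	LAMA2	ENST00000421865.3:c.4127T>A	LP
CM/CMD	RYR1	ENST00000355481.8:c.6175_6187del	LP
CM/CMD	MSTO1	ENST00000245564.2:c.1678C>T	LP
CM/CMD	PIEZ02	ENST00000302079.10:c.1345C>T	LP	probable typo for PIEZO2
CM/CMD	PIEZ02	ENST00000302079.10:c.5082+2T>C	LP	probable typo for PIEZO2
CM/CMD	CHCHD10	ENST00000484558.2:c.262-1_262dup	LP
CM/CMD	MMF	ENST00000304593.14:c.744+1G>A	LP	symbol as printed; gene unresolved
CM/CMD	NEB	ENST00000397337.6:c.736dup	LP
CM/CMD	NEB	ENST00000397345.8:c.23310del	LP
CM/CMD	LAMA2	ENST00000421865.3:c.1170C>A	LP
CM/CMD	TPM3	ENST00000271850.11:c.734G>C	LP
CM/CMD	RYR1	ENST00000355481.8:c.12323G>A	VUS
CM/CMD	BICD2	ENST00000356884.11:c.1993_1998dup	VUS
CM/CMD	ACTA1	ENST00000366683.3:c.182A>G	VUS
CM/CMD	MYH2	ENST00000245503.10:c.4809G>A	VUS
CM/CMD	GBE1	ENST00000429644.7:c.602A>G	VUS
CM/CMD	RYR1	ENST00000355481.8:c.9678G>T	VUS
CM/CMD	MSTO1	ENST00000245564.8:c.49G>C	VUS
CM/CMD	FKRP	ENST00000318584.10:c.1034G>T	VUS
CM/CMD	PLOD1	ENST00000196061.5:c.1285G>C	VUS
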