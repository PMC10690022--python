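# Novel variants reported for the genetic peripheral neuropathy cohort, transcribed
# verbatim (including the duplicated MPZ c.772C>G row counted twice in the source).
disease_category	gene_symbol	variant	acmg_class	annotation
Neuropathy	SBF2	ENST00000256190.13:c.2100+1G>A	Pathogenic
Neuropathy	NEFL	ENST00000610854.2:c.796G>T	Pathogenic
Neuropathy	HSPB1	ENST00000248553.7:c.504del	LP
Neuropathy	SH3TC2	ENST00000504517.5:c.321G>A	LP
Neuropathy	IGHMBP2	ENST00000255078.8:c.449+2T>A	LP
Neuropathy	GAN	ENST00000648994.2:c.280C>T	LP
Neuropathy	MPZ	ENST00000463290.5:c.620_623dup	LP
Neuropathy	PMP22	ENST00000312280.9:c.448_449delGGinsTT	LP
Neuropathy	NEFL	ENST00000610854.2:c.65_68delCCCGinsT	LP
Neuropathy	VRK1	ENST00000216639.8:c.1012A>T	LP
Neuropathy	MPV17	ENST00000233545.6:c.176_181del	LP
Neuropathy	PRX	ENST00000324001.8:c.1560_1562del	LP
Neuropathy	PMP2	ENST00000256103.3:c.19G>C	LP
Neuropathy	MPZ	ENST00000463290.5:c.212A>G	VUS
Neuropathy	MPZ	ENST00000672602.2:c.772C>G	VUS	row appears twice in source
Neuropathy	ATP7A	ENST00000341514.11:c.2083C>T	VUS
Neuropathy	SCN11A	ENST00000302328.9:c.1101G>T	VUS
Neuropathy	AIFM1	ENST00000287295.8:c.512T>C	VUS
Neuropathy	ATL1	ENST00000358385.12:c.1208G>C	VUS
Neuropathy	KIF1A	ENST00000648047.1:c.368A>G	VUS
Neuropathy	KMT2C	ENST00000262189.11:c.1013C>T	VUS
Neuropathy	MPZ	ENST00000672602.2:c.772C>G	VUS	row appears twice in source
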