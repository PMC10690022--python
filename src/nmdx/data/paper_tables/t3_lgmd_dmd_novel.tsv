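# Novel variants reported for the limb-girdle muscular dystrophy and
# Duchenne/Becker muscular dystrophy cohorts, transcribed verbatim.
disease_category	gene_symbol	variant	acmg_class	annotation
LGMD	GNE	ENST00000396594.8:c.1057C>T	Pathogenic
LGMD	DYSF	ENST00000258104.7:c.4558del	Pathogenic
LGMD	DYSF	ENST00000258104.7:c.3496_3508del	LP
LGMD	GNE	ENST00000396594.8:c.2196G>C	LP
LGMD	GNE	ENST00000396594.8:c.1000dup	LP
LGMD	CAV3	ENST00000343849.3:c.262T>G	LP
LGMD	DYSF	ENST00000258104.7:c.856-1G>A	LP
LGMD	HSPG2	ENST00000374676.4:c.14C>T	VUS	identified in two unrelated participants
LGMD	SYNE2	ENST00000344113.8:c.18212G>A	VUS
LGMD	DYSF	ENST00000258104.7:c.1781T>C	VUS
LGMD	DYSF	ENST00000258104.7:c.5388dup	VUS
LGMD	KIF5A	ENST00000286452.5:c.839G>T	VUS
LGMD	MYH3	ENST00000583535.6:c.3131A>T	VUS
LGMD	RYR1	ENST00000355481.8: c.2321 G>A	VUS	spacing as printed
LGMD	DMD	ENST00000343523.7:c.1859A>T	VUS
DMD/BMD	DMD	ENST00000357033.9:c.2381-1G>C	LP
DMD/BMD	DMD	ENST00000357033.9:c.4575_4579del	LP
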