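# Gene panels keyed to diagnostic categories. One row per (panel, gene).
# hpo_terms are semicolon-joined and repeated on every row of the panel.
panel_id	panel_name	category	hpo_terms	gene	mode
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	DYSF	AR
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	CAPN3	AR
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	GNE	AR
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	SGCB	AR
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	SGCA	AR
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	ANO5	AR
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	FKRP	AR
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	CAV3	AD
P_LGMD	Limb girdle muscular dystrophy	LGMD	HP:0003701;HP:0003391;HP:0008994	TTN	AR
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	GJB1	XL
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	PMP22	AD
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	MFN2	AD
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	MPZ	AD
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	SH3TC2	AR
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	PRX	AR
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	HSPB1	AD
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	IGHMBP2	AR
P_PN	Charcot-Marie-Tooth and related neuropathies	PN	HP:0009830;HP:0001761;HP:0002460	NEFL	AD
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	STAC3	AR
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	RYR1	AR
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	LAMA2	AR
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	NEB	AR
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	SELENON	AR
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	COL6A2	AD
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	COL6A3	AD
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	ACTA1	AD
P_CM_CMD	Congenital myopathy and muscular dystrophy	CM_CMD	HP:0001252;HP:0001270;HP:0002093	TPM3	AD
P_DMD_BMD	Dystrophinopathies	DMD_BMD	HP:0003707;HP:0003560;HP:0003236	DMD	XL
P_MITO	Mitochondrial myopathies	MITO	HP:0003128;HP:0000602;HP:0003546	POLG	AR
P_MITO	Mitochondrial myopathies	MITO	HP:0003128;HP:0000602;HP:0003546	OPA1	AD
P_SMA	Spinal muscular atrophy	SMA	HP:0007269;HP:0001265;HP:0002390	SMN1	AR
P_FSHD	Facioscapulohumeral muscular dystrophy	FSHD	HP:0003547;HP:0010628;HP:0008948	SMCHD1	AD
P_MYOTONIC	Myotonic dystrophies	MYOTONIC	HP:0002486;HP:0000518;HP:0002290	DMPK	AD
P_MYOTONIC	Myotonic dystrophies	MYOTONIC	HP:0002486;HP:0000518;HP:0002290	CNBP	AD
P_CMS	Congenital myasthenic syndromes	CMS	HP:0003473;HP:0000508;HP:0001605	CHRNE	AR
P_CMS	Congenital myasthenic syndromes	CMS	HP:0003473;HP:0000508;HP:0001605	RAPSN	AR
P_MND	Motor neuron diseases	MND	HP:0007354;HP:0002380;HP:0001257	SOD1	AD
P_MND	Motor neuron diseases	MND	HP:0007354;HP:0002380;HP:0001257	FUS	AD
P_OTHER	Undifferentiated neuromuscular disease	OTHER	HP:0001324;HP:0003198;HP:0003552	VCP	AD
P_OTHER	Undifferentiated neuromuscular disease	OTHER	HP:0001324;HP:0003198;HP:0003552	MYH7	AD
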