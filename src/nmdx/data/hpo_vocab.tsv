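# Category -> positive HPO term vocabulary used by the simulator and the packaged panels.
# A compact controlled map (>=3 terms per category); full ontology traversal is out of scope.
category	hpo_id	label
LGMD	HP:0003701	Proximal muscle weakness
LGMD	HP:0003391	Gowers sign
LGMD	HP:0008994	Proximal muscle atrophy
PN	HP:0009830	Peripheral neuropathy
PN	HP:0001761	Pes cavus
PN	HP:0002460	Distal muscle weakness
CM_CMD	HP:0001252	Hypotonia
CM_CMD	HP:0001270	Motor delay
CM_CMD	HP:0002093	Respiratory insufficiency
DMD_BMD	HP:0003707	Calf muscle pseudohypertrophy
DMD_BMD	HP:0003560	Muscular dystrophy
DMD_BMD	HP:0003236	Elevated circulating creatine kinase
MITO	HP:0003128	Lactic acidosis
MITO	HP:0000602	Ophthalmoplegia
MITO	HP:0003546	Exercise intolerance
SMA	HP:0007269	Spinal muscular atrophy
SMA	HP:0001265	Hyporeflexia
SMA	HP:0002390	Fasciculations of the tongue
FSHD	HP:0003547	Shoulder girdle muscle weakness
FSHD	HP:0010628	Facial palsy
FSHD	HP:0008948	Scapular winging
MYOTONIC	HP:0002486	Myotonia
MYOTONIC	HP:0000518	Cataract
MYOTONIC	HP:0002290	Frontal balding
CMS	HP:0003473	Fatigable weakness
CMS	HP:0000508	Ptosis
CMS	HP:0001605	Vocal cord paralysis
MND	HP:0007354	Amyotrophic lateral sclerosis
MND	HP:0002380	Fasciculations
MND	HP:0001257	Spasticity
OTHER	HP:0001324	Muscle weakness
OTHER	HP:0003198	Myopathy
OTHER	HP:0003552	Muscle stiffness
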