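lineage	alias	universal	canonical
mammals	OXT	OT	1
mammals	OT	OT	0
mammals	Oxy	OT	0
mammals	NPI	OT	0
mammals	AVP	VT	1
mammals	ARVP	VT	0
mammals	AVRP	VT	0
mammals	Vp	VT	0
mammals	Vsp	VT	0
mammals	NP2	VT	0
mammals	OXTR	OTR	1
mammals	AVPR1A	VTR1A	1
mammals	AVPR1a	VTR1A	0
mammals	V1aR	VTR1A	0
mammals	V1A	VTR1A	0
mammals	AVPR1B	VTR1B	1
mammals	AVPR1b	VTR1B	0
mammals	V1bR	VTR1B	0
mammals	AVPR3	VTR1B	0
mammals	VPR3	VTR1B	0
mammals	V3	VTR1B	0
mammals	VIBR	VTR1B	0
mammals	AVPR2	VTR2C	1
mammals	V2R	VTR2C	0
mammals	VPV2R	VTR2C	0
birds	MT	OT	1
birds	MST	OT	0
birds	VT	VT	1
birds	MTR	OTR	1
birds	VT3	OTR	0
birds	VT4	VTR1A	1
birds	VT4R	VTR1A	0
birds	VT2	VTR1B	1
birds	AVT2R	VTR1B	0
birds	VT1	VTR2A	1
birds	AVPR2	VTR2A	0
turtles_crocodiles	MT	OT	1
turtles_crocodiles	MST	OT	0
turtles_crocodiles	VT	VT	1
turtles_crocodiles	OXTR	OTR	1
turtles_crocodiles	Avpr2.2	VTR2A	1
frogs	MT	OT	1
frogs	MST	OT	0
frogs	VT	VT	1
frogs	MesoR	OTR	1
frogs	OXTR	OTR	0
frogs	VasR	VTR1A	1
frogs	Avpr1	VTR1A	0
frogs	V2L	VTR2A	1
frogs	Avpr2.2	VTR2A	0
fish	IT	OT	1
fish	IST	OT	0
fish	IT-1-like	OT	0
fish	IT-NP	OT	0
fish	VT	VT	1
fish	VT-NP	VT	0
fish	avpl	VT	0
fish	vsnp	VT	0
fish	ITR	OTR	1
fish	itnpr-like2	OTR	0
fish	itr2	OTR	0
fish	OXTR	OTR	0
fish	Avpr1aa	VTR1A	1
fish	Avpr1ab	VTR1A	0
fish	VasR	VTR1A	0
fish	V2bR2	VTR2A	1
fish	V2C	VTR2A	0
fish	Avpr2.2	VTR2A	0
fish	AVPR4	VTR2B	1
fish	V2B	VTR2B	0
fish	V2BR1	VTR2B	0
fish	V2RI	VTR2B	0
fish	OTRI	VTR2B	0
fish	nft	VTR2B	0
fish	avpr2	VTR2B	0
fish	AVPR2A	VTR2C	1
fish	Avpr2bb	VTR2C	0
fish	avpr2aa	VTR2C	0
fish	V2A	VTR2C	0
sharks	glumitocin	OT	1
sharks	valitocin	OT	0
sharks	aspargtocin	OT	0
sharks	neurophysin-1-like	OT	0
sharks	VT	VT	1
sharks	OXTR	OTR	1
sharks	V2bR2	VTR2A	1
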