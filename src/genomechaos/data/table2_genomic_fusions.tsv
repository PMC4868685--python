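#sample	gene_fusion	rearrangement_type
IOR/OS15	PMP22-ELOVL5	Translocation
IOR/OS15	GCC2-CCDC73	Translocation
IOR/OS15	RAI1-CLIC5	Translocation
IOR/OS15	TP53-PPRAD	Translocation
IOR/OS15	MRPL39-MAML3	Translocation and deletion
IOR/OS15	PLXNA2-RUNX1	Translocation
IOR/OS15	SCO1-CLIC5	Translocation
IOR/OS15	EIF2S1-RBM25	Deletion
IOR/OS15	BAZ1A-NUMB	Deletion
IOR/OS15	CDC5L-BTBD9	Inversion
IOR/OS15	MRPL39-NRIP1	Inversion
MG-63	DNER-ELL2	Translocation
MG-63	CLIP4-EPHB4	Translocation
MG-63	TP53-VAV1	Translocation
MG-63	TP53-EMR1	Translocation
MG-63	MROH1-PARP10	Inversion
MG-63	BNC2-MTAP	Inversion
ZK-58	CREBBP-TFAP4	Deletion
ZK-58	GDPD5-MAP6	Deletion
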