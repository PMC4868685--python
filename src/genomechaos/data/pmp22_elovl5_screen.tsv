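#cohort_sizes	rna_screen=49	dna_screen=25
#sample	cohort	assay
IOR/OS15	rna_screen	fusion qPCR
IOR/MOS	rna_screen	fusion qPCR
MHM	rna_screen	fusion qPCR
U-2 OS	rna_screen	fusion qPCR
OKTx	rna_screen	fusion qPCR
OS29	rna_screen	fusion qPCR
OS83	rna_screen	fusion qPCR
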