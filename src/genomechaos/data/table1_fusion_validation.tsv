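#fusion	rnaseq_samples	pcr_IOR_OS15	pcr_IOR_MOS	pcr_MHM	pcr_normal_bone	pcr_osteoblast	sanger
COL1A2-MMP14	IOR/OS15,IOR/OS18	+	+	+	-	-	+
FUS-LGMN	IOR/OS15,MG-63	+	+	-	-	-	+
DHFR-PABPC1	IOR/OS15	+	+	-	-	-	+
PTMA-NPM1	IOR/OS15	+	+	+	-	-	+
PMP22-ELOVL5	IOR/OS15	+	+	-	-	-	+
CDC5L-BTBD9	IOR/OS15	+	-	-	-	-	+
RAI1-CLIC5	IOR/OS15	+	-	-	-	-	+
TP53-PPRAD	IOR/OS15	+	-	-	-	-	+
MRPL39-MAML3	IOR/OS15	+	-	-	-	-	+
PLXNA2-RUNX1	IOR/OS15	+	-	-	-	-	+
EIF5A-HMGN2	IOR/OS15,MG-63,Saos-2	+	+	+	+	+	+
EEF1A1-VIM	IOR/OS15,IOR/OS18,IOR/SARG	+	+	+	+	+	+
EIF2S1-RBM25	IOR/OS15	+	-	-	-	-	+
COL1A1-HSP90AB1	IOR/OS15,MG-63	+	-	+	-	-	-
SCO1-CLIC5	IOR/OS15	+	+	+	+	+	-
CREB3L1-HNRPA	IOR/OS15	-	-	-	-	-	ND
PDZRN4-PKM2	IOR/OS15,IOR/OS18,MHM	-	-	-	-	-	ND
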