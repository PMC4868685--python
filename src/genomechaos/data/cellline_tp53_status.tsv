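#cell_line	p53_cause	tp53_location	detail
KPD	rearrangement	Intron 1	fusion transcript TP53(exon1)-DDX39B
MG-63	rearrangement	Intron 1	translocation; fusion transcripts TP53-VAV1 and TP53-EMR1
Saos-2	rearrangement	Intron 1	long deletion after exon 1; fusion TP53(exon1)-SAT2
ZK-58	rearrangement	Intron 1	t(5;17)(q13.2;p13.1); transcript retains exon 1 only
IOR/OS15	rearrangement	Intron 8	fusion TP53(exons1-8)-PPRAD; aa 1-306 retained
IOR/OS10	rearrangement	Intron 9	truncated transcript ends after exon 9 (aa 331)
IOR/OS18	rearrangement	Intron 4	t(14;17)(q32.2;p13.1); transcript retains exons 5-11 (aa 126-393)
MHM	mdm2-amplification	.	wild-type TP53; MDM2 amplification, ~10-fold overexpression
OSA	mdm2-amplification	.	wild-type TP53; MDM2 amplification, ~10-fold overexpression
IOR/SARG	mutation	.	homozygous stop mutation at aa 205
IOR/MOS	small-deletion	.	deletion at transcript bp 249-572 affecting TAD2 and DNA-binding domain
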