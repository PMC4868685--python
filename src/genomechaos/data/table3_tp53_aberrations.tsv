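#gene	sample	type	position	consequence	aberrant_af	wt_af
TP53	PD7507a	Del (7.5 Mb)	Intron 9	TSS-exon i9 deleted	40%	20%
TP53	PD7507a	Trans	Intron 9	Loss of exon i9-3'UTR	40%	.
TP53	PD7513a	Trans	Intron 1	Loss of exon2-3'UTR	40%	25%
TP53	PD7513a	Trans	Intron 1	Loss of TSS and exon1	35%	.
TP53	PD7194a	Inv (50.3 Mb)	Intron 1	Loss of exon2-3'UTR	40%	30%
TP53	PD7194a	Trans	1.8 Mb upstream TP53 TSS	Gene loss (unbalanced translocation)	30%	.
TP53	PD7197a	Small del (10 bp)	Exon5/intron5	Splice site disruption	55%	45%
TP53	PD13491a	Del (416 kb)	364 kb upstream - 31 kb downstream TP53 3'UTR	Gene loss	70%	30%
TP53	PD13492a	Trans	Intron 1	Loss of exon2-3'UTR	55%	15%
TP53	PD13492a	Trans	Intron 1	Loss of TSS and exon1	30%	.
TP53	PD13493a	Del (72 kb)	50 kb upstream - 3 kb downstream TP53	Gene loss	60%	40%
TP53	PD13496a	Trans	76 kb downstream TP53	Gene loss	50%	30%
TP53	PD13496a	Trans	2 kb upstream TP53	Gene loss	20%	.
TP53	PD7193	Del (93 kb)	Intron 1	Loss of exon2-3'UTR	40%	30%
TP53	PD7193	Trans	Intron 1	Loss of exon2-3'UTR	30%	.
TP53	PD13485a	Del (9 kb)	Intron 9	Loss of exon i9-3'UTR	20%	80%
TP53	PD13486a	Trans	Intron 1	Loss of exon2-3'UTR	75%	25%
TP53	PD13484a	SNV	c.843C>A	p.D281E	32%	68%
TP53	PD13487a	SNV	c.713G>T	p.C238F	82%	18%
TP53	PD13488a	SNV	c.764T>C	p.I255T	62%	38%
TP53	PD7196a	SNV	c.818G>T	p.R273L	47%	53%
TP53	PD13490a	SNV	c.824G>A	p.C275Y	72%	28%
MDM2	PD7508a	High level Ampl	chr12 q15	Total CN of 20	.	.
MDM2	PD7510a	High level Ampl	chr12 q15	Total CN of 60	.	.
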