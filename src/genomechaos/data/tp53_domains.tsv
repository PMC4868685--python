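#domain	start_aa	end_aa
# p53 protein, 393 aa. Coordinates are this package's working annotation of
# the canonical domain layout (transactivation domains, DNA-binding domain,
# nuclear localization signal, oligomerization domain, basic region).
TAD1	1	42
TAD2	43	63
DBD	101	292
NLS	303	322
OD	323	356
BR	363	393
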