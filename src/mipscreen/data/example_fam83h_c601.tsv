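# Worked counter-example: the recurrent FAM83H premature-termination variant
# c.601C>T p.(Gln201*) (rs189033490). Its gnomAD frequency (0.0024) exceeds
# the monoallelic threshold and it lies in coding exon 3, outside the
# last-exon interval where FAM83H truncating variants cause disease, so the
# triage cascade must exclude it twice over. The genomic coordinate below is
# a synthetic placement inside exon 3 of the hg19 locus, not a transcribed
# database coordinate.
family_id	gene	genomic	hgvs_c	hgvs_p	zygosity	cadd	gnomad_af
EX1	FAM83H	chr8:g.144812435G>A	c.601C>T	p.(Gln201*)	het	40	0.0024
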