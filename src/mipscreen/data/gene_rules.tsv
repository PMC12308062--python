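# Gene-specific qualification rules applied after the CADD/MAF cascade.
# truncating_last_exon: truncating (nonsense/frameshift) variants qualify
# only inside [start, end) (0-based half-open, hg19). For FAM83H this is the
# large last coding exon (exon 5 of NM_198488.5; minus-strand gene, so the
# last exon sits at the low-coordinate end of the locus).
gene	rule	contig	start	end
FAM83H	truncating_last_exon	chr8	144806102	144811200
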