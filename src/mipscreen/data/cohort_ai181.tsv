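# Variant-level records for the solved families of a 181-proband isolated-AI
# screening cohort (hg19 nomenclature). One row per variant per family.
# mode_table: inheritance table the family was reported under (XL/AD/AR).
# zygosity: het, hom or hemi. structural: 1 for whole-exon events.
# primary: 1 if the variant belongs to the family's diagnostic gene, 0 for
#   the second-gene findings of the digenic families.
# cadd / gnomad_af: empty when not scored / absent from gnomAD.
# classification: reported ACMG label, carried read-only (P/LP/VOUS/LB).
# sex: XY for hemizygous carriers, XX otherwise.
family_id	mode_table	gene	genomic	hgvs_c	hgvs_p	zygosity	cadd	gnomad_af	classification	structural	primary	sex
8	XL	AMELX	chrX:g.11314944G>A	c.100G>A	p.(Glu34Lys)	het	33		VOUS	0	1	XX
9	XL	AMELX	chrX:g.11316220T>C	c.103-3T>C	p.?	hemi	15		LP	0	1	XY
21	XL	AMELX	chrX:g.11316954del	c.473del	p.(Pro158Hisfs*31)	hemi			P	0	1	XY
27	XL	AMELX	chrX:g.11316366del	c.155del	p.(Pro52Leufs*2)	het			P	0	1	XX
32	XL	AMELX	chrX:g.11316220T>C	c.103-3T>C	p.?	het	15		LP	0	1	XX
38	XL	AMELX	chrX:g.11316366del	c.155del	p.(Pro52Leufs*2)	hemi			P	0	1	XY
65	XL	AMELX	chrX:g.11316927A>C	c.446A>C	p.(Gln149Pro)	hemi	19	0.00001	VOUS	0	1	XY
1	AD	COL17A1	chr10:g.105811247C>T	c.2030G>A	p.(Gly677Asp)	het	26		LP	0	1	XX
4	AD	COL17A1	chr10:g.105798865del	c.2912del	p.(Pro971Glnfs*95)	het	33		LP	0	1	XX
5	AD	DLX3	chr17:g.48069185_48069186del	c.561_562del	p.(Tyr188Glnfs*13)	het			P	0	1	XX
7	AD	COL17A1	chr10:g.105796271G>A	c.3397C>T	p.(Arg1133Cys)	het	33		VOUS	0	1	XX
11	AD	COL17A1	chr10:g.105796802C>T	c.3277+1G>A	p.?	het	35		P	0	1	XX
13	AD	COL17A1	chr10:g.105811266C>T	c.2011G>A	p.(Gly671Ser)	het	25		LP	0	1	XX
14	AD	ENAM	chr4:g.71503505A>T	c.535-2A>T	p.?	het	33		LP	0	1	XX
16	AD	AMBN	chr4:g.71465278C>G	c.209C>G	p.(Ser70*)	het	36	0.00010	P	0	1	XX
18	AD	COL17A1	chr10:g.105830245_105830254del	c.541_550del	p.(Asn181Profs*13)	het	28		P	0	1	XX
22	AD	FAM83H	chr8:g.144810257G>T	c.1374C>A	p.(Tyr458*)	het	38		P	0	1	XX
24	AD	COL17A1	chr10:g.105795287del	c.3456del	p.(Pro1154Leufs*97)	het	21	0.00002	P	0	1	XX
26	AD	COL17A1	chr10:g.105793715_105793716del	c.4147_4148del	p.(Ser1383Hisfs*71)	het	34		P	0	1	XX
30	AD	ENAM	chr4:g.71497387del	c.55del	p.(Val19Tyrfs*6)	het	33		LP	0	1	XX
33	AD	ENAM	chr4:g.71497439del	c.107del	p.(Asn36Ilefs*22)	het			P	0	1	XX
34	AD	ENAM	chr4:g.71501548G>A	c.472-1G>A	p.?	het	25		LP	0	1	XX
35	AD	ENAM	chr4:g.71497439del	c.107del	p.(Asn36Ilefs*22)	het			P	0	1	XX
36	AD	COL17A1	chr10:g.105816859C>A	c.1339G>T	p.(Gly447Cys)	het	24	0.00070	VOUS	0	1	XX
39	AD	FAM83H	chr8:g.144809494G>A	c.2137C>T	p.(Gln713*)	het	36		LP	0	1	XX
40	AD	AMBN	chr4:g.71465278C>G	c.209C>G	p.(Ser70*)	het	36	0.00010	P	0	1	XX
41	AD	DLX3	chr17:g.48072078G>C	c.285C>G	p.(Tyr95*)	het	36		P	0	1	XX
43	AD	FAM83H	chr8:g.144810439G>A	c.1192C>T	p.(Gln398*)	het	36		LP	0	1	XX
44	AD	AMBN	chr4:g.71459104G>A	c.76G>A	p.(Ala26Thr)	het	26		LP	0	1	XX
45	AD	FAM83H	chr8:g.144810277G>A	c.1354C>T	p.(Gln452*)	het	37		LP	0	1	XX
48	AD	COL17A1	chr10:g.105831793G>A	c.460C>T	p.(Arg154*)	het	36		P	0	1	XX
49	AD	COL17A1	chr10:g.105795287del	c.3456del	p.(Pro1154Leufs*97)	het	21	0.00002	P	0	1	XX
55	AD	FAM83H	chr8:g.144810268G>A	c.1363C>T	p.(Gln455*)	het	37		P	0	1	XX
56	AD	COL17A1	chr10:g.105795035G>A	c.3605C>T	p.(Ser1202Leu)	het	27	0.00001	VOUS	0	1	XX
57	AD	FAM83H	chr8:g.144810658G>A	c.973C>T	p.(Arg325*)	het	36		P	0	1	XX
63	AD	FAM83H	chr8:g.144810710_144810711del	c.923_924del	p.(Leu308Argfs*16)	het			LP	0	1	XX
2	AR	ACP4	chr19:g.51294940C>T	c.331C>T	p.(Arg111Cys)	hom	26	0.00012	LP	0	1	XX
3	AR	FAM20A	chr17:g.66538249_66538252del	c.987_990del	p.(Cys330Alafs*51)	hom	33		LP	0	1	XX
6	AR	MMP20	chr11:g.102480660C>G	c.625G>C	p.(Glu209Gln)	hom	30	0.00006	LP	0	1	XX
12	AR	WDR72	chr15:g.53908077dup	c.2332dup	p.(Met778Asnfs*4)	het	24	0.00001	P	0	1	XX
12	AR	WDR72	chr15:g.54025229G>A	c.118C>T	p.(Gln40*)	het	40	0.00002	P	0	1	XX
15	AR	MMP20	chr11:g.102465490T>A	c.954-2A>T	p.?	hom	25	0.00110	P	0	1	XX
17	AR	MMP20	chr11:g.102480660C>G	c.625G>C	p.(Glu209Gln)	hom	27	0.00007	P	0	1	XX
19	AR	AMBN	chr4:g.71465278C>G	c.209C>G	p.(Ser70*)	hom	36	0.00010	P	0	1	XX
20	AR	MMP20	chr11:g.102480660C>G	c.625G>C	p.(Glu209Gln)	hom	27	0.00007	P	0	1	XX
23	AR	SLC24A4	SLC24A4:del_exons15-17	Deletion of Exons 15-17		hom				1	1	XX
25	AR	MMP20	chr11:g.102479824T>A	c.655A>T	p.(Asn219Tyr)	hom	27		VOUS	0	1	XX
28	AR	AMBN	chr4:g.71465278C>G	c.209C>G	p.(Ser70*)	het	36	0.00010	P	0	1	XX
28	AR	AMBN	chr4:g.71467135T>C	c.295T>C	p.(Tyr99His)	het	26	0.00008	LP	0	1	XX
37	AR	ITGB6	chr2:g.161052847C>A	c.226G>T	p.(Glu76*)	hom	39	0.00001	P	0	1	XX
42	AR	RELT	chr11:g.73101947T>C	c.268T>C	p.(Cys90Arg)	hom	26		LP	0	1	XX
46	AR	MMP20	chr11:g.102479803G>A	c.676C>T	p.(His226Tyr)	hom	28		LP	0	1	XX
47	AR	MMP20	chr11:g.102465490T>A	c.954-2A>T	p.?	hom	25	0.00110	P	0	1	XX
50	AR	ACP4	chr19:g.51294940C>T	c.331C>T	p.(Arg111Cys)	het	26	0.00012	P	0	1	XX
50	AR	ACP4	chr19:g.51295044del	c.435del	p.(Val146Trpfs*7)	het	32		P	0	1	XX
51	AR	SLC24A4	chr14:g.92920382T>C	c.1019T>C	p.(Leu340Pro)	hom	25		VOUS	0	1	XX
52	AR	WDR72	chr15:g.53907717G>A	c.2686C>T	p.(Arg896*)	hom	36	0.00003	P	0	1	XX
53	AR	FAM20A	chr17:g.66535488G>A	c.1351C>T	p.(Gln451*)	hom	47		LP	0	1	XX
54	AR	WDR72	chr15:g.53994432_53994433del	c.1467_1468del	p.(Val491Aspfs*8)	hom		0.00007	P	0	1	XX
58	AR	MMP20	chr11:g.102465490T>A	c.954-2A>T	p.?	het	25	0.00110	P	0	1	XX
58	AR	MMP20	chr11:g.102477286del	c.933del	p.(Glu311Aspfs*59)	het	32	0.00001	P	0	1	XX
59	AR	WDR72	chr15:g.53992117_53992118del	c.1600_1601del	p.(Cys534Argfs*2)	het			P	0	1	XX
59	AR	WDR72	chr15:g.53907897C>A	c.2506G>T	p.(Glu836*)	het	37		P	0	1	XX
60	AR	ACP4	chr19:g.51297211T>C	c.845T>C	p.(Met282Thr)	hom	27		VOUS	0	1	XX
61	AR	FAM20A	chr17:g.66551883G>A	c.406C>T	p.(Arg136*)	het	39	0.00004	P	0	1	XX
61	AR	FAM20A	chr17:g.66538120A>C	c.1109+6T>G	p.?	het	23		LP	0	1	XX
62	AR	MMP20	chr11:g.102465490T>A	c.954-2A>T	p.?	hom	25	0.00110	P	0	1	XX
64	AR	ENAM	chr4:g.71508226G>A	c.1083G>A	p.(Trp361*)	hom	36		LP	0	1	XX
66	AR	WDR72	chr15:g.54003125C>T	c.883G>A	p.(Ala295Thr)	hom	20		LP	0	1	XX
25	AR	COL17A1	chr10:g.105799724A>T	c.2788+7T>A	p.?	het	17	0.00006	VOUS	0	0	XX
62	AR	COL17A1	chr10:g.105830262G>A	c.529C>T	p.(Arg177Trp)	het	27	0.00005	VOUS	0	0	XX
4	AD	MMP20	chr11:g.102495959G>A	c.92C>T	p.(Pro31Leu)	het	21	0.00460	LB	0	0	XX
4	AD	MMP20	chr11:g.102477309C>T	c.910G>A	p.(Ala304Thr)	het	25	0.00156	VOUS	0	0	XX
18	AD	MMP20	chr11:g.102495959G>A	c.92C>T	p.(Pro31Leu)	het	21	0.00460	LB	0	0	XX
18	AD	MMP20	chr11:g.102477309C>T	c.910G>A	p.(Ala304Thr)	het	25	0.00156	VOUS	0	0	XX
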