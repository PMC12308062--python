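# 19-gene isolated amelogenesis imperfecta panel (hg19).
# Coordinates converted once from 1-based inclusive to 0-based half-open.
# modes: per-gene inheritance modes (AD, AR, XL; comma-separated).
symbol	transcript	contig	start	end	cytoband	modes
LAMB3	NM_000228.3	chr1	209788214	209825770	1q32.2	AD
ITGB6	NM_000888.5	chr2	160956181	161056783	2q24.2	AR
AMTN	NM_001286731.2	chr4	71384285	71398460	4q13.3	AD
AMBN	NM_016519.6	chr4	71457972	71473005	4q13.3	AD,AR
ENAM	NM_031889.3	chr4	71494460	71512541	4q13.3	AD,AR
ODAPH	NM_001206981.2	chr4	76481275	76491095	4q21.1	AR
FAM83H	NM_198488.5	chr8	144806102	144815949	8q24.3	AD
COL17A1	NM_000494.4	chr10	105791043	105845638	10q25.1	AD
MMP20	NM_004771.4	chr11	102447562	102496063	11q22.2	AR
RELT	NM_152222.2	chr11	73087443	73108519	11q13.4	AR
GPR68	NM_001177676.2	chr14	91698875	91711048	14q32.11	AR
SLC24A4	NM_153646.4	chr14	92789508	92967825	14q32.12	AR
WDR72	NM_182758.4	chr15	53805937	54051860	15q21.3	AR
SP6	NM_199262.3	chr17	45922273	45933063	17q21.32	AD
DLX3	NM_005220.3	chr17	48067368	48072588	17q21.33	AD
FAM20A	NM_017565.4	chr17	66531256	66597508	17q24.2	AR
ACP4	NM_033068.3	chr19	51293671	51298476	19q13.33	AR
KLK4	NM_004917.5	chr19	51409606	51414651	19q13.41	AR
AMELX	NM_182680.1	chrX	11311532	11318881	Xp22.2	XL
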