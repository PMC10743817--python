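gene	transcript	variants	origin	outcome	recurrent	study_id	gestational_age_weeks
PADI6	NM_207421.4	c.1793A>G (p.Asn598Ser);c.2045G>A (p.Arg682Gln)	inherited	miscarriage		R55	
PADI6	NM_207421	c.122C>T (p.Ala41Val)	unknown	miscarriage		R49	
STIL	NM_001048166.1	c.1231C>G (p.His411Asp);c.3370A>G (p.Met1124Val)	uncertain	miscarriage		R65	
STIL	NM_001048166	c.1012C>T (p.His338Tyr)	inherited	miscarriage		R51	
DYNC2H1	NM_001080463.1	c.2819-14A4G	inherited	termination		R46	
DYNC2H1	NM_001080463.1	c.7577T4G (p.Ile2526Ser)	inherited	termination		R46	
DYNC2H1	NM_001377.3	c.6047A>G (p.Tyr2016Cys);c.6551A>T (p.Asp2184Val)	inherited	miscarriage		R33	
FGFR2	NM_000141	c.940-1G>A	unknown	fetal_demise		R48	
FGFR2	NM_022970.3	c.764G>A (p.Arg255Gln)	inherited	neonatal_death		R34	
FGFR2	NM_022970.3	c.758C>G (p.Pro253Arg)	de_novo	termination		R34	
FGFR3	NM_000142	c.1537G>T (p.Asp513Tyr)	unknown	miscarriage		R52	
FGFR3	NM_000142	c.742C>T (p.Arg248Cys)	unknown	miscarriage		R52	
FGFR3	NM_000142	c.1118A>G (p.Tyr373Cys)	unknown	termination		R26	
FRAS1	NM_025074	c.8537C>A (p.Ala2846Asp)	inherited	miscarriage		R51	
FRAS1	NM_025074.7	c.1918C>T (p.Arg640Cys);c.5205C>A (p.His1735Gln)	unknown	termination		R26	
GREB1L	NM_001142966.2	c.5614dupA (p.Thr1872Asnfs*)	de_novo	termination		R34	
GREB1L	NM_001142966	c.1305dupA (p.Asp436Argfs*32)	unknown	miscarriage		R52	
LZTR1	ENST00000215739.8	c.902G>T (p.Gly301Val)	de_novo	termination		R34	
LZTR1	NM_006767	c.2317G>A (p.Val773Met)	unknown	miscarriage		R72	
PIEZO1	NM_001142864	c.1264C>T (p.Gln422Ter)	uncertain	miscarriage		R72	
PIEZO1	NM_001142864	c.2035G>T (p.Glu679X)	uncertain	termination		R48	
PIEZO1	NM_001142864.3	c.3206G>A (p.Trp1069Ter);c.6208A>C (p.Lys2070Gln)	inherited	termination		R73	
PIEZO1	NM_001142864	c.30_31delAC (p.Leu10fs)	uncertain	miscarriage		R51	
PIK3R2	NM_005027	c.1117G>A (p.Gly373Arg)	unknown	fetal_demise		R52	
PIK3R2	NM_005027	c.1690A>G (p.Lys564Glu)	unknown	miscarriage		R48	
PTPN11	NM_002834	c.174C>A (p.Asn58Lys)	unknown	fetal_demise		R48	
PTPN11	NM_002834.4	c.218C>T (p.Thr73Ile)	de_novo	neonatal_death		R34	
COL2A1	NM_001844.5	c.3864_3865delCT (p.Cys1289Pfs*)	inherited	termination		R34	
COL2A1	NM_001844.5	c.3490G>T (p.Gly1164Cys)	de_novo	miscarriage		R26	
FOXP3	NM_014009.3	c.1009C>T (p.Arg337Ter)	inherited	rpl	true	R74	
FOXP3	NM_014009.3	c.906delT (p.Asp303fs*87)	inherited	fetal_death		R75	
FOXP3	NM_014009.3	c.1009C>T (p.Arg337X)	inherited	miscarriage		R76	
FOXP3	NM_014009.3	c.1033C>T (p.Leu345Phe)	inherited	miscarriage		R77	
FOXP3	NM_014009.3	c.1189CNT (p.Arg397Trp)	inherited	miscarriage		R78	
FOXP3	NM_014009.3	c.319_320delTC	inherited	miscarriage		R78	
NEB	NM_001164507	c.20974delA (p.Val6993Serfs*8)	uncertain	miscarriage		R72	
NEB	NM_001271208	c.24094C>T (p.Arg8032Ter);c.20098C>A (p.Leu6700Ile)	uncertain	miscarriage		R52	
RYR1	NM_000540.2	c.14130-2A>G;c.9221C>T (p.Ser3074Phe)	inherited	termination		R46	
RYR1	NM_000540.2	c.6721C>T (p.Arg2241Ter)	inherited	miscarriage		R79	
RYR1	NM_000540.2	c.2097_2123del (p.Glu699_Gly707del)	inherited	termination		R79	
RYR1	NM_000540.2	c.7043delGA (p.Glu2347del)	inherited	termination		R79	
RYR2	NM_001035.2	c.409C>T (p.Arg137Trp);c.4652A>G (p.Asn1551Ser)	inherited	rpl	true	R39	
RYR2	NM_001035.2	c.12526G>A (p.Val4176Met)	inherited	stillbirth		R34	
SCN5A	NM_001160161	c.3749C>T (p.Thr1250Met)	inherited	miscarriage		R51	
SCN5A	NM_198056	c.5393G>A (p.Trp1798Ter)	unknown	fetal_demise		R52	
SCN5A	NM_198056.3	c.1663G>T (p.Glu555Ter)	unknown	stillbirth		R50	
SCN5A	NM_198056.3	c.1858C>T (p.Arg620Cys)	unknown	stillbirth		R50	
SCN5A	NM_198056.3	c.5350G>A (p.Glu1784Lys)	unknown	stillbirth		R50	
GBE1	NM_000158	c.467G>A (p.Arg156His);c.-35_-54del	uncertain	miscarriage		R51	
GBE1	NM_000158	c.1064G>A (p.Arg355His)	inherited	fetal_demise		R47	
GBE1	NM_000158	c.1543C>T (p.Arg515Cys)	inherited	fetal_demise		R47	
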