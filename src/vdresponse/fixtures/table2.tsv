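gene	effect	fold_change	sequence	position	similarity
TIA1	increased	26	GGTTCAagcAGTTCT	-19259	RANKL
ZNF287	increased	6.8	GGGCGAgcaAGGGGA	-33162	MIS
Y-RNA	increased	2	GGGTTAtggAGACCA	-13579	Insulin receptor
Y-RNA	increased	2	AGACCAgcaAGGGCA	-15357	C-fos
Y-RNA	increased	2	AGGGGAgtgGGCTCA	-5398	Lrp5
Y-RNA	increased	2	AGAACTgttTGAACT	2000	RANKL,CYP24A1
Y-RNA	increased	2	AGGGCAatgGGCTCA	-17578	C-fos,Lrp5
Y-RNA	increased	2	TGAACTgccGGGCCA	-16195	RANKL,CYP24A1
Y-RNA	increased	2	GGGGGAggcGGGCGA	-16589	Osteocalcin
CETN3	increased	1.9	GGGTTCcacAGTTCT	-7715	RANKL,Lrp5
CETN3	increased	1.9	AGGCGAggcAGGGGA	257	MIS
CETN3	increased	1.9	AGACCAgctGGGGCA	7743	Osteocalcin,Insulin receptor
MINPP1	increased	1.6	AGGGCAgggGGCGGG	-33	C-fos
MINPP1	increased	1.6	AGGTTAgttGGGTCA	-7722	Insulin receptor
MINPP1	increased	1.6	GGTTCAagcAGTTCT	-15303	RANKL,Osteopontin,Lrp5
PUS3	increased	1.6	AGGGCAagaGGGGCA	-1027	Osteocalcin,Ros
PUS3	increased	1.6	GGTTCAagcAGTTCT	-11623	RANKL,Osteopontin
PUS3	increased	1.6	AGGGCAaaaAGTTCG	-23238	C-fos
PUS3	increased	1.6	AGGCCAacaGGGGCA	-28062	Osteocalcin,Insulin receptor
PUS3	increased	1.6	AGGACTacaGGGACA	-38442	hWise,MIS
ZDHHC16	increased	1.5	GGTTCAagcAGTTCT	-43597	RANKL
PTRH2	increased	1.5	TCATTCataAGGGCA	-6751	RANKL,C-fos
NUDCD1	increased	1.5	GGTTGAagaGGGTGA	-18094	RANKL
COPB2	increased	1.5	TGAACTcttAGGTGA	-28579	RANKL,CYP24A1
TRIM27	increased	1.5	GGTTCAagcAGTTCT	-10940	RANKL,Osteopontin,Lrp5
HSPH1	increased	1.5	GGGGTAatcCAGACA	-185	PTH
HSPH1	increased	1.5	AGGCCAgttGGGGCA	-13744	Osteocalcin,Insulin receptor
HSPH1	increased	1.5	GGGTCAgacAGGGCA	-15275	Insulin receptor,Ros
KEAP1	increased	1.5	AGGCCAaggGGGGCA	-12008	Osteocalcin,Insulin receptor
KEAP1	increased	1.5	AGGGCAatgGGCTCA	-17578	C-fos,Lrp5
KEAP1	increased	1.5	TGAACTgccGGGCCA	-16195	RANKL,CYP24A1
KEAP1	increased	1.5	GGGGGAggcGGGCGA	-16589	Osteocalcin
CD83	decreased	2	AGTTCAaacAGTTCT	2237	RANKL,CYP24A1
CD83	decreased	2	GGGCCAgaaGGGTTA	-12371	Osteocalcin
CD83	decreased	2	GGTTCAagcAGTTCT	-72447	RANKL,Osteopontin,Lrp5
CD83	decreased	2	AGGTCAgagAGGTGA	-41941	CYP24A1
CD83	decreased	2	AGGTGAgaaAGTTCA	-27226	RANKL,CYP24A1
CD83	decreased	2	AGTTCAgagGGGTGA	-84403	RANKL,CYP24A1
CD83	decreased	2	GGGTGAtctAGTTGA	-106730	CYP24A1
CD83	decreased	2	GGGTCAtgaGGGTCA	-121008	Insulin receptor
TNFAIP3	decreased	1.5	AGGACAaatGGGACA	-71377	hWise
TNFAIP3	decreased	1.5	TGCCCTgacTGGTCT	-115872	C-fos
TNFAIP3	decreased	1.5	AGGTGAatgGGGTGA	-108862	CYP24A1
TNFAIP3	decreased	1.5	AGTTGAtgaAGTTGA	-142558	CYP24A1
NFKBIA	decreased	1.5	GGGTGAcatGGGTGA	-31881	MIS
TNNI3K	decreased	1.6	GGGTCAgaaACAACC	-51	Insulin receptor,RANKL
TNNI3K	decreased	1.6	AGGTGAaacAGGTCA	-29062	CYP24A1
TNNI3K	decreased	1.6	AGGGCGgaaGGGGGA	-23892	CYP24A1
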