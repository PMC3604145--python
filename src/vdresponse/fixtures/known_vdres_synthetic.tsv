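source	half1	half2	full_sequence
RANKL	GGTTCA	AGTTCT	GGTTCAagcAGTTCT
CYP24A1	AGGTGA	AGGGCG	AGGTGAgtgAGGGCG
Osteopontin	GGTTCA	GGTTCA	GGTTCAcgaGGTTCA
Osteocalcin	GGGTGA	GGGGCA	GGGTGAacgGGGGCA
C-fos	AGGGCA	AGGGCA
Lrp5	AGGGGA	GGCTCA
MIS	GGGCGA	AGGGGA
Insulin receptor	GGGTCA	AGACCA
Ros	AGGGCA	GGGGCA
PTH	GGGGTA	CAGACA
hWise	AGGACA	GGGACA
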