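name	half1	spacer_len	half2
consensus	RGKTSA	3	RGKTSA
RANKL	GGTTCA	3	AGTTCT
CYP24A1	AGGTGA	3	AGGGCG
Osteopontin	GGTTCA	3	GGTTCA
Osteocalcin	GGGTGA	3	GGGGCA
C-fos	AGGGCA	3	AGGGCA
Lrp5	AGGGGA	3	GGCTCA
MIS	GGGCGA	3	AGGGGA
Insulin receptor	GGGTCA	3	AGACCA
Ros	AGGGCA	3	GGGGCA
PTH	GGGGTA	3	CAGACA
hWise	AGGACA	3	GGGACA
RANKL-v2	GGGTTC	3	AGTTCT
RANKL-v3	TCATTC	3	AGGGCA
C-fos-v2	AGGGCA	3	GGCGGG
Insulin receptor-v2	GGGTCA	3	ACAACC
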