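dose	n	n_women	age_mean	age_sd	serum_before_mean	serum_before_sd	serum_after_mean	serum_after_sd
400	3	2	27.3	2.0	18.3	1.1	24.0	5.2
2000	5	1	26.0	5.1	24.0	10.7	33.8	7.8
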