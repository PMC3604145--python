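gene	window_upstream_bp
ACTB	100000
GAPDH	100000
B2M	100000
HPRT1	100000
TBP	100000
PPIA	100000
RPLP0	100000
RPL13A	100000
GUSB	100000
PGK1	100000
UBC	100000
TFRC	100000
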