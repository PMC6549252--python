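strain	SolV	Fur	Rib	Fdl	Ice	Yel	Phi	V4	Kam1
SolV	100
Fur	89.1	100
Rib	89.4	100	100
Fdl	89.7	100	100	100
Ice	88.4	98.9	99	100	100
Yel	55	60.7	60.7	55.4	61	100
Phi	17.5	17.6	17.6	21.6	21.6	20.1	100
V4	17.1	17.1	17.1	17.1	19.6	20.4	20.1	100
Kam1	49.8	54.8	54.8	49.9	49.9	50.4	20.8	17.1	100
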