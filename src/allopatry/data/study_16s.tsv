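strain	SolV	Fur	Rib	Fdl	Ice	Yel	Phi	V4	Kam1
SolV	100
Fur	100	100
Rib	100	100	100
Fdl	100	100	100	100
Ice	100	100	100	100	100
Yel	99.5	99.5	99.5	99.5	99.5	100
Phi	98.7	98.7	98.7	98.7	98.7	98.7	100
V4	98.6	98.6	98.6	98.6	98.7	98.7	99.2	100
Kam1	99.7	99.7	99.7	99.7	99.7	99.5	98.7	98.7	100
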