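# PARSE-style atomic radii (A), element-keyed; polar-hydrogen model
# element	radius
H	1.00
C	1.70
N	1.50
O	1.40
S	1.85
P	1.90
FE	1.30
MG	1.45
NA	1.85
CL	1.75
K	2.00
ZN	1.40
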