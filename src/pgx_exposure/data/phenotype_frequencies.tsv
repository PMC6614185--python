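gene	phenotype	frequency
CYP3A5	N	0.002
CYP3A5	I	0.116
CYP3A5	P	0.882
CYP2B6	N	0.560
CYP2B6	I	0.386
CYP2B6	P	0.054
CYP2C9	N	0.649
CYP2C9	I	0.309
CYP2C9	P	0.042
CYP2C19	N	0.675
CYP2C19	I	0.233
CYP2C19	P	0.026
CYP2C19	U	0.066
CYP2D6	N	0.599
CYP2D6	I	0.259
CYP2D6	P	0.122
CYP2D6	U	0.02
DPYD	N	0.930
DPYD	I	0.050
DPYD	P	0.020
FVL	N	0.964
FVL	Het	0.036
FVL	Hom	0.000
HLA-A*31:01	N	0.922
HLA-A*31:01	Het	0.076
HLA-A*31:01	Hom	0.002
HLA-B*15:02	N	0.994
HLA-B*15:02	Het	0.006
HLA-B*15:02	Hom	0.000
HLA-B*57:01	N	0.936
HLA-B*57:01	Het	0.064
HLA-B*57:01	Hom	0.000
HLA-B*5801	N	0.876
HLA-B*5801	Het	0.106
HLA-B*5801	Hom	0.018
SLCO1B1	N	0.705
SLCO1B1	I	0.265
SLCO1B1	P	0.030
TPMT	N	0.795
TPMT	I	0.205
TPMT	P	0.000
VKORC1	N	0.373
VKORC1	I	0.506
VKORC1	P	0.121
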