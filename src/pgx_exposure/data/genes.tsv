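gene	category	reference_allele	reference_function	cn_aware
CYP3A5	enzyme	*3	inactive	0
CYP2B6	enzyme	*1	normal	0
CYP2C9	enzyme	*1	normal	0
CYP2C19	enzyme	*1	normal	0
CYP2D6	enzyme	*1	normal	1
DPYD	enzyme	*1	normal	0
FVL	carrier	non-carrier	non-carrier	0
HLA-A*31:01	carrier	non-carrier	non-carrier	0
HLA-B*15:02	carrier	non-carrier	non-carrier	0
HLA-B*57:01	carrier	non-carrier	non-carrier	0
HLA-B*5801	carrier	non-carrier	non-carrier	0
SLCO1B1	transporter	*1	normal	0
TPMT	enzyme	*1	normal	0
VKORC1	sensitivity	*1	normal	0
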