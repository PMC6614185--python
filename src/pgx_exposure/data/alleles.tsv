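gene	star_name	rsids	risk_alleles	function	frequency
CYP3A5	*1	rs776746	A	normal	0.06
CYP3A5	*6	rs10264272	A	inactive	0.00
CYP3A5	*7	rs41303343	TA	inactive	0.00
CYP2B6	*6	rs3745274	T	decreased	0.25
CYP2C9	*2	rs1799853	T	decreased	0.13
CYP2C9	*3	rs1057910	C	inactive	0.07
CYP2C19	*2	rs4244285	A	inactive	0.14
CYP2C19	*3	rs4986893	A	inactive	0.00
CYP2C19	*17	rs12248560	T	increased	0.23
CYP2D6	*2	rs16947	T	normal	0.32
CYP2D6	*4	rs3892097;rs1065852	A;T	inactive	0.21
CYP2D6	*10	rs1065852	T	decreased	0.02
CYP2D6	*17	rs28371706	T	decreased	0.00
CYP2D6	*41	rs28371725	A	decreased	0.09
CYP2D6	*42	rs72549346	GGT	inactive	0.00
DPYD	*2A	rs3918290	A	inactive	0.007
DPYD	*13	rs55886062	G	inactive	0.002
DPYD	c.1236G>A	rs56038477	A	decreased	0.021
DPYD	c.2846A>T	rs67376798	T	decreased	0.006
FVL	Leiden	rs6025	A	risk-tag	0.018
HLA-A*31:01	A*31:01	rs1061235	T	risk-tag	0.022
HLA-B*15:02	B*15:02	rs3909184;rs2844682	C;A	risk-tag	0.006
HLA-B*57:01	B*57:01	rs2395029	G	risk-tag	0.032
HLA-B*5801	B*5801	rs3134792;rs4713518	G;G	risk-tag	0.0631
SLCO1B1	*5	rs4149056	C	decreased	0.163
TPMT	*2	rs1800462	C	inactive	0.001
TPMT	*3A	rs1800460;rs1142345	A;G	inactive	0.021
TPMT	*3B	rs1800460	A	inactive	0.017
TPMT	*3C	rs1142345	G	inactive	0.063
VKORC1	*2	rs9923231	A	increased	0.373
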