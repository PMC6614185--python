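gene	function_pair	copy_number	phenotype
CYP3A5	normal|normal	any	N
CYP3A5	inactive|normal	any	I
CYP3A5	inactive|inactive	any	P
CYP2B6	normal|normal	any	N
CYP2B6	decreased|normal	any	I
CYP2B6	decreased|decreased	any	P
CYP2C9	normal|normal	any	N
CYP2C9	decreased|normal	any	I
CYP2C9	inactive|normal	any	I
CYP2C9	decreased|decreased	any	P
CYP2C9	decreased|inactive	any	P
CYP2C9	inactive|inactive	any	P
CYP2C19	normal|normal	any	N
CYP2C19	inactive|normal	any	I
CYP2C19	inactive|increased	any	I
CYP2C19	inactive|inactive	any	P
CYP2C19	increased|normal	any	U
CYP2C19	increased|increased	any	U
CYP2D6	normal|normal	any	N
CYP2D6	decreased|normal	any	N
CYP2D6	inactive|normal	any	I
CYP2D6	decreased|decreased	any	I
CYP2D6	decreased|inactive	any	I
CYP2D6	inactive|inactive	any	P
CYP2D6	normal|normal	gt2	U
CYP2D6	decreased|normal	gt2	U
CYP2D6	inactive|normal	gt2	U
DPYD	normal|normal	any	N
DPYD	decreased|normal	any	I
DPYD	inactive|normal	any	I
DPYD	decreased|decreased	any	P
DPYD	decreased|inactive	any	P
DPYD	inactive|inactive	any	P
FVL	non-carrier|non-carrier	any	N
FVL	non-carrier|risk-tag	any	Het
FVL	risk-tag|risk-tag	any	Hom
HLA-A*31:01	non-carrier|non-carrier	any	N
HLA-A*31:01	non-carrier|risk-tag	any	Het
HLA-A*31:01	risk-tag|risk-tag	any	Hom
HLA-B*15:02	non-carrier|non-carrier	any	N
HLA-B*15:02	non-carrier|risk-tag	any	Het
HLA-B*15:02	risk-tag|risk-tag	any	Hom
HLA-B*57:01	non-carrier|non-carrier	any	N
HLA-B*57:01	non-carrier|risk-tag	any	Het
HLA-B*57:01	risk-tag|risk-tag	any	Hom
HLA-B*5801	non-carrier|non-carrier	any	N
HLA-B*5801	non-carrier|risk-tag	any	Het
HLA-B*5801	risk-tag|risk-tag	any	Hom
SLCO1B1	normal|normal	any	N
SLCO1B1	decreased|normal	any	I
SLCO1B1	decreased|decreased	any	P
TPMT	normal|normal	any	N
TPMT	inactive|normal	any	I
TPMT	inactive|inactive	any	P
VKORC1	normal|normal	any	N
VKORC1	increased|normal	any	I
VKORC1	increased|increased	any	P
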