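row_id	genes	drugs	actionable_set	therapeutic_area	exposures	column_a_printed_pct	risky_printed	share_printed_pct	column_a_derivable
CYP3A5	CYP3A5	Tacrolimus	N+I	other	261514	11.85	30983	0.25	1
CYP2B6	CYP2B6	Efavirenz	I+P	infectious	27154	43.98	11941	0.10	1
CYP2C9	CYP2C9	Phenytoin	I+P	psychiatry/neurology	50133	35.1	17597	0.14	1
CYP2C19	CYP2C19	Citalopram;Clopidogrel;Escitalopram;Esomeprazole;Imipramine;Lansoprazole;Omeprazole;Pantoprazole;Sertraline;Voriconazole	I+P+U	mixed	15471291	9.88	1528438	12.35	0
CYP2D6	CYP2D6	Amitriptyline;Aripiprazole;Clomipramine;Codeine;Doxepin;Flecainide;Haloperidol;Imipramine;Metoprolol;Nortriptyline;Oxycodone;Paroxetine;Pimozide;Propafenone;Tamoxifen;Tramadol;Venlafaxine;Zuclopenthixol	I+P+U	mixed	18638754	40.1	7467420	60.31	1
DPYD	DPYD	Capecitabine;Fluorouracil;Tegafur	I+P	oncology	275923	7.00	19301	0.16	1
FVL	FVL	Contraceptives with Estrogen	Het+Hom	endocrinology	2561819	3.6	92226	0.74	1
HLA-carbamazepine	HLA-A*31:01;HLA-B*15:02	Carbamazepine	Het+Hom	psychiatry/neurology	245493	38.54	96063	0.16	0
HLA-B*57:01	HLA-B*57:01	Abacavir;Flucloxacillin	Het+Hom	infectious	1729046	6.4	110659	0.89	1
HLA-B*5801	HLA-B*5801	Allopurinol	Het+Hom	other	692108	12.45	86168	0.70	1
SLCO1B1	SLCO1B1	Atorvastatin;Simvastatin	I+P	cardiovascular	9226089	29.52	2723364	22.00	1
TPMT	TPMT	6-Mercaptopurine;Azathioprine;Thioguanine	I+P	oncology	193641	20.5	39696	0.32	1
VKORC1	VKORC1	Acenocoumarol;Phenprocoumon	P	cardiovascular	1931864	12.05	232755	1.88	1
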