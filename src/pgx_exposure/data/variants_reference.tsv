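gene	allele	change_label	rsids	maf_cohort	maf_other	p_printed
CYP3A5	*1	6986A > G	rs776746	0.06	0.008
CYP3A5	*6	14690G > A	rs10264272	0.00	0.001
CYP3A5	*7	Deletion	rs41303343	0.00	0.00
CYP2B6	*6	516G > T	rs3745274	0.25	0.30
CYP2C9	*2	430C > T	rs1799853	0.13	0.11	0.29
CYP2C9	*3	1075A > C	rs1057910	0.07	0.20	0.0001
CYP2C19	*2	19154G > A	rs4244285	0.14	0.14	0.94
CYP2C19	*3	17948G > A	rs4986893	0.00	0.00	1.00
CYP2C19	*17	-806C > T	rs12248560	0.23	0.20	0.15
CYP2D6	*2	2850C > T	rs16947	0.32	0.34	0.43
CYP2D6	*4	1846G > A	rs3892097	0.21	0.20	0.50
CYP2D6	*10	100C > T	rs1065852	0.23	0.21	0.29
CYP2D6	*17	1023C > T	rs28371706	0.00	0.00	1.00
CYP2D6	*41	2988G > A	rs28371725	0.09	0.10	0.74
CYP2D6	*42	3259insGT	rs72549346	0.00	0.00	1.00
DPYD	*2A	1905+1G > A	rs3918290	0.007	0.01	0.59
DPYD	*13	1679T > G	rs55886062	0.002	0.00	1.00
DPYD	c.1236G>A	1236G > A	rs56038477	0.021	0.25
DPYD	c.2846A>T	2846 A > T	rs67376798	0.006	0.007
FVL	Leiden	1691G > A	rs6025	0.018	0.03
HLA-A*31:01	A*31:01	29913298A > T	rs1061235	0.022	0.03
HLA-B*15:02	B*15:02	30699384G > C and 30946148G > A	rs3909184;rs2844682	0.006	0.00
HLA-B*57:01	B*57:01	31431780T > G	rs2395029	0.032	0.034
HLA-B*5801	B*5801	31312326T > G and 32257337A > G	rs3134792;rs4713518	0.0631	0.06
SLCO1B1	*5	521T > C	rs4149056	0.163	0.14	0.24
TPMT	*2	238G > C	rs1800462	0.001	0.00	1.00
TPMT	*3A	460G > A and 719A > G	rs1800460;rs1142345	0.021	0.025
TPMT	*3B	460G > A	rs1800460	0.038	0.04	0.94
TPMT	*3C	719A > G	rs1142345	0.084	0.07	0.19
VKORC1	*2	-1639G > A	rs9923231	0.373	0.37	0.14
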