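rsid	chrom	pos	ref	alt	change_label
rs3918290	1	97915614	G	A	1905+1G > A
rs55886062	1	97981343	T	G	1679T > G
rs56038477	1	98039419	G	A	1236G > A
rs67376798	1	97547947	A	T	2846A > T
rs6025	1	169519049	G	A	1691G > A
rs1800462	6	18143955	G	C	238G > C
rs1800460	6	18139228	G	A	460G > A
rs1142345	6	18130918	A	G	719A > G
rs1061235	6	29913298	A	T	29913298A > T
rs3909184	6	30699384	G	C	30699384G > C
rs2844682	6	30946148	G	A	30946148G > A
rs3134792	6	31312326	T	G	31312326T > G
rs2395029	6	31431780	T	G	31431780T > G
rs4713518	6	32257337	A	G	32257337A > G
rs41303343	7	99250393	T	TA	Deletion
rs10264272	7	99262835	G	A	14690G > A
rs776746	7	99270539	G	A	6986A > G
rs4986893	10	96540410	G	A	17948G > A
rs4244285	10	96541616	G	A	19154G > A
rs12248560	10	96521657	C	T	-806C > T
rs1799853	10	96702047	C	T	430C > T
rs1057910	10	96741053	A	C	1075A > C
rs4149056	12	21331549	T	C	521T > C
rs9923231	16	31107689	G	A	-1639G > A
rs3745274	19	41512841	G	T	516G > T
rs72549346	22	42523600	G	GGT	3259insGT
rs28371725	22	42523805	G	A	2988G > A
rs16947	22	42523943	C	T	2850C > T
rs3892097	22	42524947	G	A	1846G > A
rs28371706	22	42525772	C	T	1023C > T
rs1065852	22	42526694	C	T	100C > T
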