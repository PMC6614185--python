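drug	therapeutic_area	items_issued_thousands
6-Mercaptopurine	oncology	136
Abacavir	infectious	116
Acenocoumarol	cardiovascular	9149
Allopurinol	other	6210
Aripiprazole	psychiatry/neurology	1625
Azathioprine	oncology	1093
Capecitabine	oncology	297
Carbamazepine	psychiatry/neurology	3033
Clopidogrel	cardiovascular	10195
Contraceptives with Estrogen	endocrinology	7842
Efavirenz	infectious	145
Flecainide	cardiovascular	1806
Flucloxacillin	infectious	2459
Fluorouracil	oncology	312
Haloperidol	psychiatry/neurology	2678
Metoprolol	cardiovascular	61224
Proton Pump Inhibitors (PPI)	gastroenterology	110147
Opioids	analgesic/anaesthesiology	28559
Phenprocoumon	cardiovascular	1821
Phenytoin	psychiatry/neurology	1028
Pimozide	psychiatry/neurology	599
Propafenone	cardiovascular	97
SSRI	psychiatry/neurology	27424
Simvastatin and Atorvastatin	cardiovascular	80653
Tacrolimus	other	977
Tamoxifen	oncology	1193
Tegafur	oncology	0.812
Thioguanine	oncology	53
Tricyclic antidepressants	psychiatry/neurology	15034
Venlafaxine	psychiatry/neurology	7698
Voriconazole	infectious	24
Zuclopenthixol	psychiatry/neurology	722
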