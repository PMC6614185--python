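year	sex	age_band	users
2015	men	0-4	9916
2015	men	5-14	24324
2015	men	15-24	69230
2015	men	25-44	377305
2015	men	45-64	1412311
2015	men	65-74	1046979
2015	men	75+	951502
2015	women	0-4	8240
2015	women	5-14	36071
2015	women	15-24	185101
2015	women	25-44	562921
2015	women	45-64	1599198
2015	women	65-74	1071277
2015	women	75+	1345702
2017	men	0-4	11156
2017	men	5-14	23894
2017	men	15-24	70700
2017	men	25-44	366669
2017	men	45-64	1418338
2017	men	65-74	977954
2017	men	75+	1029667
2017	women	0-4	10245
2017	women	5-14	35511
2017	women	15-24	442109
2017	women	25-44	551128
2017	women	45-64	1459159
2017	women	65-74	1123780
2017	women	75+	1378342
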