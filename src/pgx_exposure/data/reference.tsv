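key	value
total_prescribed_thousands	1600241
total_pgx_issued_thousands_printed	384351
pgx_share_printed_pct	24.02
insured_population	11400000
european_ancestry_fraction	0.85
users_total_printed	9700000
total_exposures_printed	51304829
total_risky_printed	12380754
n_cohort	498
n_mizzi	349
cyp2d6_ultrarapid_freq	0.02
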