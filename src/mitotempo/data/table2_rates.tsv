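source	rate_e8	ci_low_e8	ci_high_e8
ref23_modern_calibration	1.67	1.37	1.97
this_study_oldest_period	1.91	1.72	2.10
ref8_a	1.92	1.16	2.68
ref7	2.23	1.71	2.75
ref10	2.40	1.70	3.20
ref24	2.53	1.80	3.20
ref8_b	2.67	2.16	3.16
ref9	2.74	2.44	3.01
this_study_youngest_period	4.33	3.90	4.82
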