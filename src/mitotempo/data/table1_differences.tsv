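period	mean_age_bp	age_sd	M_mean	M_sd	M_n	N_mean	N_sd	N_n	R_mean	R_sd	R_n	total_mean	total_sd	total_n	expected
1	1119	483	1.67	0.56	3	0.34	3.61	18	0.65	1.62	119	0.63	0.03	140	0.63
2	2652	1025	1.13	1.63	15	0.50	1.38	6	1.16	2.19	18	1.05	0.04	39	1.49
3	4294	372	0.78	1.48	10	0.42	1.87	9	2.33	2.08	28	1.63	0.12	47	2.42
4	5164	479	1.52	1.03	5	1.35	1.70	4	1.51	1.83	28	1.51	0.08	37	2.91
5	6936	458	1.86	1.79	8	2.90	1.93	8	3.61	3.01	32	3.20	0.09	48	3.90
6	8504	822	3.00	2.83	2	3.08	2.39	9	3.36	2.02	29	3.28	0.02	40	4.79
7	13017	1533	4.25	0.97	5	2.60	0.14	2	4.59	2.31	17	4.35	0.12	24	7.33
8	15977	1254	NA	NA	NA	NA	NA	NA	6.50	1.50	11	6.50	1.50	11	8.99
9	29638	3020	10.00	0.71	2	NA	NA	NA	11.23	2.28	13	11.07	0.01	15	16.69
10	40160	4658	14.13	2.31	3	13.00	3.61	5	15.67	4.97	6	14.39	0.33	14	22.61
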