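name	ppm_lo	ppm_hi	normo_mean	normo_sd	malb_mean	malb_sd
cholesterol	0.60	0.75	3.17	0.44	2.95	0.44
lipid_ch3	0.80	0.90	7.26	0.39	7.35	0.47
isoleucine_leucine	0.92	0.97	2.41	0.10	2.31	0.15
isoleucine_valine	0.98	1.00	0.82	0.04	0.78	0.06
valine	1.03	1.05	0.65	0.03	0.61	0.05
lipid_ch2n	1.20	1.32	12.59	2.08	14.78	2.91
lactate	1.32	1.35	1.83	0.38	2.09	0.45
alanine	1.46	1.49	1.12	0.06	1.05	0.08
lipid_beta_ch2	1.55	1.60	1.67	0.16	1.82	0.23
isoleucine	1.92	1.97	1.52	0.07	1.44	0.09
aminobutyrate_lipid	1.98	2.03	2.31	0.18	2.48	0.25
n_acetylglutamine	2.10	2.15	1.17	0.07	1.10	0.09
pyruvate	2.34	2.38	0.62	0.05	0.58	0.06
hydroxyisovalerate	2.34	2.41	1.05	0.08	0.96	0.09
glutamine	2.43	2.47	0.56	0.04	0.51	0.06
dimethylamine	2.65	2.80	2.03	0.11	1.99	0.13
trimethylamine	2.90	2.95	0.59	0.05	0.54	0.06
albumin	2.95	3.00	0.72	0.06	0.66	0.07
creatine_creatinep	3.02	3.05	0.46	0.03	0.43	0.05
choline	3.18	3.20	0.46	0.03	0.43	0.05
phosphocholine	3.21	3.22	1.02	0.42	0.92	0.37
proline	3.32	3.37	0.30	0.04	0.28	0.04
glucose	3.45	3.48	0.35	0.07	0.38	0.11
leucine	3.68	3.72	0.60	0.07	0.61	0.10
creatine_p	3.93	3.97	0.61	0.05	0.58	0.08
creatinine	4.03	4.08	0.72	0.05	0.75	0.13
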