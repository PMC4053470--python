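name	ppm_lo	ppm_hi	role
region_0.50_0.60	0.50	0.60	analysis_region
cholesterol	0.60	0.75	analysis_region
region_0.75_0.80	0.75	0.80	analysis_region
lipid_ch3	0.80	0.90	analysis_region
region_0.90_0.92	0.90	0.92	analysis_region
isoleucine_leucine	0.92	0.97	analysis_region
region_0.97_0.98	0.97	0.98	analysis_region
isoleucine_valine	0.98	1.00	analysis_region
region_1.00_1.03	1.00	1.03	analysis_region
valine	1.03	1.05	analysis_region
region_1.05_1.20	1.05	1.20	analysis_region
lipid_ch2n	1.20	1.32	analysis_region
lactate	1.32	1.35	analysis_region
region_1.35_1.46	1.35	1.46	analysis_region
alanine	1.46	1.49	analysis_region
region_1.49_1.55	1.49	1.55	analysis_region
lipid_beta_ch2	1.55	1.60	analysis_region
region_1.60_1.92	1.60	1.92	analysis_region
isoleucine	1.92	1.97	analysis_region
region_1.97_1.98	1.97	1.98	analysis_region
aminobutyrate_lipid	1.98	2.03	analysis_region
region_2.03_2.10	2.03	2.10	analysis_region
n_acetylglutamine	2.10	2.15	analysis_region
region_2.15_2.34	2.15	2.34	analysis_region
pyruvate	2.34	2.38	analysis_region
region_2.38_2.41	2.38	2.41	analysis_region
region_2.41_2.43	2.41	2.43	analysis_region
glutamine	2.43	2.47	analysis_region
region_2.47_2.65	2.47	2.65	analysis_region
dimethylamine	2.65	2.80	analysis_region
region_2.80_2.90	2.80	2.90	analysis_region
trimethylamine	2.90	2.95	analysis_region
albumin	2.95	3.00	analysis_region
region_3.00_3.02	3.00	3.02	analysis_region
creatine_creatinep	3.02	3.05	analysis_region
region_3.05_3.18	3.05	3.18	analysis_region
choline	3.18	3.20	analysis_region
region_3.20_3.21	3.20	3.21	analysis_region
phosphocholine	3.21	3.22	analysis_region
region_3.22_3.32	3.22	3.32	analysis_region
proline	3.32	3.37	analysis_region
region_3.37_3.45	3.37	3.45	analysis_region
glucose	3.45	3.48	analysis_region
region_3.48_3.68	3.48	3.68	analysis_region
leucine	3.68	3.72	analysis_region
region_3.72_3.93	3.72	3.93	analysis_region
creatine_p	3.93	3.97	analysis_region
region_3.97_4.03	3.97	4.03	analysis_region
creatinine	4.03	4.08	analysis_region
region_4.08_4.40	4.08	4.40	analysis_region
region_4.40_4.70	4.40	4.70	analysis_region
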