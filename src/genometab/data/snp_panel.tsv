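snp_id	chrom	gene	model	beta	maf	major_allele	minor_allele
rs174611	11	FADS2	ADD	0.1759	0.35	C	T
rs174577	11	FADS2	ADD	0.1755	0.35	A	C
rs174616	11	FADS2	ADD	0.0904	0.40	G	A
rs174546	11	FADS1	ADD	0.1562	0.35	C	T
rs511895	11	CAT	ADD	-0.1369	0.30	A	G
rs662799	11	APOA5	ADD	0.2792	0.12	A	G
rs651821	11	APOC3	DOM	0.2649	0.12	T	C
rs3759347	12	GNB3	ADD	0.1643	0.30	G	A
rs10492025	12	RPH3A	ADD	0.1411	0.30	C	T
rs1129649	12	GNB3	ADD	0.1246	0.40	T	C
rs1566441	16	BBS2	ADD	-0.1302	0.45	A	G
rs11644094	16	MT3	REC	0.1121	0.35	T	G
rs8044769	16	FTO	DOM	-0.1306	0.45	T	C
rs4359	17	ACE	ADD	-0.1316	0.45	T	C
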