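rsid	chrom	pos	gene	risk_allele	other_allele	consequence	maf	imputation_r2	genotyped
rs3795958	2	26635489	CCDC164	G	A	missense	0.35	NA	1
rs12623642	2	26642219	CCDC164	T	C	missense	0.42	NA	1
rs2277046	5	13717471	DNAH5	G	A	missense	0.49	NA	1
rs10513155	5	13802166	DNAH5	T	C	missense	0.33	NA	1
rs1530498	5	13929842	DNAH5	G	A	utr3	0.38	NA	1
rs1530496	5	13931340	DNAH5	A	G	utr3	0.31	NA	1
rs2285943	7	21583128	DNAH11	T	G	missense	0.44	NA	1
rs10224537	7	21639861	DNAH11	G	T	missense	0.36	NA	1
rs2214326	7	21752446	DNAH11	A	G	missense	0.40	NA	1
rs7971	7	21941485	DNAH11	G	C	missense	0.32	NA	1
rs10250905	7	37893459	TXNDC3	C	T	missense	0.47	NA	1
rs600753	15	55790530	DYX1C1	G	A	missense	0.43	NA	1
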