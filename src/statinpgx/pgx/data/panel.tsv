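# schema_version: 1
# Genotyping panel: one row per assayed variant.  `allele` is the star allele
# (or annotation label) defined by carrying the `alt` base at `rsid`;
# `function` uses the closed vocabulary no/decreased/normal/increased/annotation.
# `activity_value` is the per-allele activity score for activity-score genes
# (CYP2D6, CYP2C9, CYP1A2); "." elsewhere.  `used_in_phenotype` marks variants
# that enter phenotype assignment; annotation-only variants are carried but
# never change a phenotype.
# CYP2B6 *4 (rs2279343) is intentionally absent from phenotype assignment:
# only *5 and *9 participate for this gene.
gene	rsid	ref	alt	allele	function	activity_value	used_in_phenotype
SLCO1B1	rs2306283	A	G	*1B	normal	.	yes
SLCO1B1	rs4149056	T	C	*5	decreased	.	yes
SLCO1B1	rs4149015	G	A	c.-910G>A	annotation	.	no
SLCO1B1	rs11045879	T	C	rs11045879	annotation	.	no
CYP3A5	rs776746	A	G	*3	no	.	yes
CYP3A5	rs10264272	C	T	*6	no	.	yes
SLC22A1	rs72552763	GAT	del	*2	decreased	.	yes
SLC22A1	rs12208357	C	T	*3	decreased	.	yes
SLC22A1	rs34059508	G	A	*5	decreased	.	yes
ABCB1	rs1045642	C	T	C3435T	annotation	.	yes
ABCB1	rs2032582	G	T	G2677T/A	annotation	.	yes
ABCB1	rs1128503	C	T	C1236T	annotation	.	yes
ABCB1	rs10276036	T	C	1000-44G>T	annotation	.	yes
ABCB1	rs3842	T	C	rs3842	annotation	.	yes
CYP2D6	rs3892097	G	A	*4	no	0	yes
CYP2D6	rs28371725	C	T	*41	decreased	0.5	yes
CYP2D6	rs1065852	C	T	*10	decreased	0.25	yes
CYP2C19	rs4244285	G	A	*2	no	.	yes
CYP2C19	rs12248560	C	T	*17	increased	.	yes
CYP2C9	rs1799853	C	T	*2	decreased	0.5	yes
CYP2C9	rs1057910	A	C	*3	no	0	yes
CYP2B6	rs3745274	G	T	*9	decreased	.	yes
CYP2B6	rs3211371	C	T	*5	normal	.	yes
CYP1A2	rs2069514	G	A	*1C	decreased	0.5	yes
CYP1A2	rs762551	C	A	*1F	increased	1.5	yes
CYP1A2	rs2470890	C	T	*1B	normal	1	yes
UGT2B7	rs7439366	T	C	*2	decreased	.	yes
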