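sample_id	chrom	pos	gene_id	major_count	total_count	mean_NM	mean_MQ
S1	chrX	2000	GENE1	16	20	6	176
S1	chrX	2001	GENE1	28	35	0	200.5
S1	chrX	2002	GENE1	48	60	3	254
S1	chrX	2003	GENE1	17	20	2	190
S1	chrX	2004	GENE1	30	35	1	210
S1	chrX	2005	GENE1	55	60	6	240
S1	chrX	2006	GENE2	18	20	0	176
S1	chrX	2007	GENE2	25	35	3	199
S1	chrX	2008	GENE2	31	60	4	182
S1	chrX	2009	GENE2	20	20	5	230
S2	chrX	2010	GENE1	29	35	6	177
S2	chrX	2011	GENE1	50	60	2	188
S2	chrX	2012	GENE1	13	20	1	251
S2	chrX	2013	GENE2	33	35	0	222
S2	chrX	2014	GENE2	45	60	3	204
S2	chrX	2015	GENE2	12	20	4	186
S1	chrX	3000	GENE1	24	30	7	200
S1	chrX	3001	GENE1	25	30	7	250
S2	chrX	3002	GENE2	22	30	7	199
S2	chrX	3003	GENE2	27	30	7	235
S1	chrX	4000	GENE1	21	30	2	175
S1	chrX	4001	GENE2	26	30	2	175
S2	chrX	4002	GENE2	19	30	2	175
S1	chrX	5000	GENE1	15	19	1	200
S1	chrX	5001	GENE1	18	19	1	212
S2	chrX	5002	GENE2	10	19	1	233
S2	chrX	5003	GENE2	17	19	1	245
S1	chrX	1000	GENE1	32	40	0	210
S1	chrX	1001	GENE1	35	40	0	210
S2	chrX	1002	GENE2	38	40	0	210
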