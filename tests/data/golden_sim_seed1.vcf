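##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##contig=<ID=sim_scaffold_1>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	pop1_01	pop1_02	pop1_03	pop1_04	pop1_05	pop1_06	pop1_07	pop1_08	pop1_09	pop1_10	pop1_11	pop2_01	pop2_02	pop2_03	pop2_04	pop2_05	pop2_06	pop2_07
sim_scaffold_1	1	.	A	T	.	PASS	.	GT:DP	0/0:10	0/0:10	1/1:10	0/0:10	0/1:10	0/0:10	1/1:10	0/1:10	./.:.	1/1:10	0/1:10	1/1:10	0/0:10	./.:.	0/0:10	0/1:10	1/1:10	1/1:10
sim_scaffold_1	2	.	A	T	.	PASS	.	GT:DP	./.:.	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10	0/1:10	1/1:10	1/1:10	1/1:10	1/1:10	1/1:10
sim_scaffold_1	3	.	A	T	.	PASS	.	GT:DP	1/1:10	1/1:10	1/1:10	1/1:10	0/1:10	0/1:10	1/1:10	0/1:10	1/1:10	0/1:10	1/1:10	0/0:10	0/1:10	0/0:10	0/0:10	0/1:10	0/0:10	0/0:10
sim_scaffold_1	4	.	A	T	.	PASS	.	GT:DP	1/1:10	1/1:10	1/1:10	0/1:10	1/1:10	1/1:10	0/1:10	1/1:10	1/1:10	1/1:10	1/1:10	0/1:10	1/1:10	./.:.	0/1:10	1/1:10	./.:.	0/1:10
sim_scaffold_1	5	.	A	T	.	PASS	.	GT:DP	1/1:10	0/1:10	0/1:10	0/0:10	0/0:10	0/1:10	0/0:10	0/0:10	0/1:10	0/1:10	1/1:10	1/1:10	0/0:10	0/1:10	1/1:10	1/1:10	1/1:10	1/1:10
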