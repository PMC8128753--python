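gene_id	exon_id	order_index	chrom	exon_start	exon_end	mean_log2_NZO	mean_log2_C3H	log2_ratio	deviation	splicing_prob	gene_arh	gene_p	significant
G55	G55.E04	4	chr1	1116001	1116200	5.275586192	6.863005993	1.587419801	1.596121222	0.4188354263	0.179510974	0.0119760479	True
G17	G17.E04	4	chr1	344001	344200	6.196143903	7.629421405	1.433277502	1.465608586	0.2680345327	0.1070786741	0.02794411178	True
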