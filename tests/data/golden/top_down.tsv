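gene_id	mean_log2_NZO	mean_log2_C3H	log2_ratio	ratio	wilcoxon_p	bh_q	present_NZO	present_C3H	de_flag	direction
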