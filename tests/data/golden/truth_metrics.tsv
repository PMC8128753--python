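analysis	metric	value
de	sensitivity	0.8888888889
de	specificity	1
de	fpr	0
de	auroc	1
as	sensitivity	1
as	specificity	0.9814814815
as	fpr	0.01851851852
as	auroc	1
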