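cultivar	ascomycota	basidiomycota	asco_or_basidio	other_fungi	total
A_fourcroydes	1927	797	19	253	2996
A_sisalana	3012	1036	23	242	4313
hybrid_11648	1986	1179	18	250	3433
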