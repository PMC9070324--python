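cultivar	n_fungal_transcripts	mean_length_bp	n50_bp	max_cds_bp	min_cds_bp
A_fourcroydes	2996	545	579	3099	258
A_sisalana	4313	540	570	3210	255
hybrid_11648	3433	529	552	2649	264
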