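cultivar	hsp_pct_of_fungal
A_fourcroydes	6.21
A_sisalana	4.92
hybrid_11648	5.71
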