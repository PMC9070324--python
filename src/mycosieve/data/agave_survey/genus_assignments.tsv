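cultivar	talaromyces_assigned
A_fourcroydes	291
A_sisalana	662
hybrid_11648	371
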