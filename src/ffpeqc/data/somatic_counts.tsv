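tissue	n_ff_somatic	n_ffpe_somatic	n_overlap
colon	436	458	165
liver	394	333	53
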