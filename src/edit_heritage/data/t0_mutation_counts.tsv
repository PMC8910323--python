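n_examined	n_fuct1_mutant	n_xylt1_mutant	n_both_loci
248	56	62	51
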