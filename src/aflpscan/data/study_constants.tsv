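key	value
total_markers	3839
polymorphic_markers	3318
informative_markers	2054
n_populations	21
n_individuals	444
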