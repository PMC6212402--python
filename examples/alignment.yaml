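# Alignment of the optimal background state with the principal noise axis,
# as a function of the number of driver nodes.
n_list: [100]
nd_list: [10, 50, 100]
t: 10.0
topology: scale_free
b_variants: [identity]
realizations: 10
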