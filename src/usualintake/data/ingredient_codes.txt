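58100110
27510110
53420000
51101010
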