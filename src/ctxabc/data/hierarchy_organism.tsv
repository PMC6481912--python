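mouse	O01.200
transgenic mouse	O01.200.100
rat	O01.300
human	O01.400
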