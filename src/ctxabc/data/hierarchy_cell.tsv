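t-cell	A11.118.637.555
neuron	A08.663
human periodontal ligament cell	A11.329.700
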