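glucose	D09.400.410
l-tyrosine	D12.125.967
melatonin	D06.472.891
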