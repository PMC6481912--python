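snca	X
phgdh	O
ins	O
bche	O
c9orf72	O
mcidas	X
src	O
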