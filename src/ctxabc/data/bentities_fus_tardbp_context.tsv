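sod1	X
gli3	O
c9orf72	O
vapb	O
mapt	O
optn	O
ang	O
grn	O
taf15	O
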