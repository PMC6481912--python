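app	O
bace1	O
bche	O
c9orf72	O
clu	X
cr1	O
ctsd	O
cyp46a1	O
gfap	O
grn	X
hfe	O
ins	O
mcidas	X
phgdh	O
picalm	O
prnp	X
rcan1	O
sars2	X
snca	X
tardbp	O
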