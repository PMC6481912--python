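PMID	Sentence_ID	Text	Entities	Clauses
23829269	1	Hsf-1 affects podocyte markers NPHS1, NPHS2 and WT1 in a transgenic mouse model of TTRVal30Met-related amyloidosis.	[0:5:gene:Hsf-1:nr5a1][31:36:gene:NPHS1:nphs1][38:43:gene:NPHS2:nphs2][48:51:gene:WT1:wt1][57:73:organism:transgenic mouse:transgenicmouse][103:114:disease:amyloidosis:amyloidosis]	[52:114:prepositional]
23829269	8	Nephrin, podocin and WT1 gene expression levels were unaffected by the Hsf-1 carrier status.	[21:24:gene:WT1:wt1][71:76:gene:Hsf-1:nr5a1]	
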