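PMID	Sentence_ID	Entity1	Entity1OfficialSymbol	Entity2	Entity2OfficialSymbol	Negation	Voice	Verb	Re_Type	CELL	DRUG	DISEASE	ORGANISM
23829269	1	hsf-1	nr5a1	nphs1	nphs1	POSITIVE	ACTIVE	affect	AFFECTS	NoData	NoData	amyloidosis	transgenicmouse
23829269	8	wt1	wt1	hsf-1	nr5a1	POSITIVE	ACTIVE	unaffected	AFFECTS	NoData	NoData	NoData	NoData
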