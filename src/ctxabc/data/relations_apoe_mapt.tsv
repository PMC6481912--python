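PMID	Sentence_ID	Entity1	Entity1OfficialSymbol	Entity2	Entity2OfficialSymbol	Negation	Voice	Verb	Re_Type	CELL	DRUG	DISEASE	ORGANISM
9100001	1	Apoe	apoe	ins	ins	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	glucose	NoData	NoData
9100002	1	Apoe	apoe	ins	ins	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	glucose	NoData	NoData
9100003	1	Apoe	apoe	ins	ins	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	glucose	NoData	NoData
9100004	1	ins	ins	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	glucose	NoData	NoData
9100005	1	Apoe	apoe	c9orf72	c9orf72	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	frontotemporaldementia	NoData
9100006	1	Apoe	apoe	c9orf72	c9orf72	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	frontotemporaldementia	NoData
9100007	1	Apoe	apoe	c9orf72	c9orf72	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	frontotemporaldementia	NoData
9100008	1	c9orf72	c9orf72	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	frontotemporaldementia	NoData
9100009	1	Apoe	apoe	snca	snca	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	parkinsondisease	NoData
9100010	1	Apoe	apoe	snca	snca	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	parkinsondisease	NoData
9100011	1	Apoe	apoe	snca	snca	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	parkinsondisease	NoData
9100012	1	snca	snca	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	parkinsondisease	NoData
9100013	1	Apoe	apoe	snca	snca	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	supranuclearpalsy,progressive	NoData
9100014	1	snca	snca	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	supranuclearpalsy,progressive	NoData
9100015	1	Apoe	apoe	snca	snca	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	multiplesystematrophy	NoData
9100016	1	snca	snca	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	multiplesystematrophy	NoData
9100017	1	Apoe	apoe	phgdh	phgdh	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	dementia	NoData
9100018	1	Apoe	apoe	phgdh	phgdh	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	dementia	NoData
9100019	1	phgdh	phgdh	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	dementia	NoData
9100020	1	Apoe	apoe	bche	bche	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	glucose	NoData	NoData
9100021	1	Apoe	apoe	bche	bche	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	glucose	NoData	NoData
9100022	1	bche	bche	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	glucose	NoData	NoData
9100023	1	Apoe	apoe	src	src	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	l-tyrosine	NoData	NoData
9100024	1	Apoe	apoe	src	src	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	l-tyrosine	NoData	NoData
9100025	1	Apoe	apoe	src	src	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	l-tyrosine	NoData	NoData
9100026	1	src	src	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	l-tyrosine	NoData	NoData
9100027	1	Apoe	apoe	mcidas	mcidas	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	dementia	NoData
9100028	1	mcidas	mcidas	Mapt	mapt	POSITIVE	ACTIVE	associate	ASSOCIATION	NoData	NoData	dementia	NoData
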