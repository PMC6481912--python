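EntityA	EntityB	EntityC	AB_CELL	AB_DRUG	AB_DISEASE	AB_ORGANISM	BC_CELL	BC_DRUG	BC_DISEASE	BC_ORGANISM	Similarity
apoe	ins	mapt	NoData	glucose	NoData	NoData	NoData	glucose	NoData	NoData	1.000000
apoe	c9orf72	mapt	NoData	NoData	frontotemporaldementia	NoData	NoData	NoData	frontotemporaldementia	NoData	1.000000
apoe	snca	mapt	NoData	NoData	parkinsondisease	NoData	NoData	NoData	parkinsondisease	NoData	1.000000
apoe	snca	mapt	NoData	NoData	parkinsondisease	NoData	NoData	NoData	parkinsondisease	NoData	1.000000
apoe	phgdh	mapt	NoData	NoData	dementia	NoData	NoData	NoData	dementia	NoData	1.000000
apoe	snca	mapt	NoData	NoData	supranuclearpalsy,progressive	NoData	NoData	NoData	supranuclearpalsy,progressive	NoData	1.000000
apoe	c9orf72	mapt	NoData	NoData	frontotemporaldementia	NoData	NoData	NoData	frontotemporaldementia	NoData	1.000000
apoe	snca	mapt	NoData	NoData	parkinsondisease	NoData	NoData	NoData	parkinsondisease	NoData	1.000000
apoe	bche	mapt	NoData	glucose	NoData	NoData	NoData	glucose	NoData	NoData	1.000000
apoe	c9orf72	mapt	NoData	NoData	frontotemporaldementia	NoData	NoData	NoData	frontotemporaldementia	NoData	1.000000
apoe	src	mapt	NoData	l-tyrosine	NoData	NoData	NoData	l-tyrosine	NoData	NoData	1.000000
apoe	phgdh	mapt	NoData	NoData	dementia	NoData	NoData	NoData	dementia	NoData	1.000000
apoe	snca	mapt	NoData	NoData	multiplesystematrophy	NoData	NoData	NoData	multiplesystematrophy	NoData	1.000000
apoe	src	mapt	NoData	l-tyrosine	NoData	NoData	NoData	l-tyrosine	NoData	NoData	1.000000
apoe	ins	mapt	NoData	glucose	NoData	NoData	NoData	glucose	NoData	NoData	1.000000
apoe	ins	mapt	NoData	glucose	NoData	NoData	NoData	glucose	NoData	NoData	1.000000
apoe	src	mapt	NoData	l-tyrosine	NoData	NoData	NoData	l-tyrosine	NoData	NoData	1.000000
apoe	bche	mapt	NoData	glucose	NoData	NoData	NoData	glucose	NoData	NoData	1.000000
apoe	mcidas	mapt	NoData	NoData	dementia	NoData	NoData	NoData	dementia	NoData	1.000000
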