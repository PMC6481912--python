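dementia	C10.228.140.380
alzheimer disease	C10.228.140.380.100
huntington disease	C10.228.140.380.300
frontotemporal dementia	C10.228.140.380.266
parkinson disease	C10.228.662.600.400
supranuclear palsy, progressive	C10.228.662.700
multiple system atrophy	C10.228.662.550
amyotrophic lateral sclerosis	C10.574.562.250
amyloidosis	C18.452.284
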