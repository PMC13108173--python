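mirna	gene
miR-499a	ZZZ3
miR-3651	ZZZ3
miR-328	ZZZ3
miR-486	ZZZ3
miR-339	ZZZ3
miR-767	ZZZ3
miR-483	ZZZ3
miR-767	MDM2
miR-483	MDM2
miR-339	MDM2
miR-425	MDM2
miR-339	SOD2
miR-425	SOD2
miR-483	SOD2
miR-153	RAN
miR-483	RAN
miR-339	RAN
miR-483	XIAP
miR-153	XIAP
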