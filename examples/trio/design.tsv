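sample_id	group
AP1	AP
BC1	BC
CP1	CP
HC1	HEALTHY
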