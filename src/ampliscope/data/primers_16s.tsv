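name	direction	sequence	region
27F-YM	forward	AGAGTTTGATYMTGGCTCAG	V1-V2
338R	reverse	TGCTGCCTCCCGTAGGAGT	V1-V2
341F	forward	CCTACGGGNGGCWGCAG	V3-V4
806RB	reverse	GGACTACNVGGGTWTCTAAT	V3-V4
515F	forward	GTGYCAGCMGCCGCGGTA	V4
806RB	reverse	GGACTACNVGGGTWTCTAAT	V4
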