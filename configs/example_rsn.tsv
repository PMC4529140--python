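region_label	group_label
r00-L	DMN
r00-R	DMN
r01-L	DMN
r01-R	DAN
r02-L	DAN
r02-R	DAN
r03-L	VN
r03-R	VN
r04-L	AN
r04-R	AN
r05-L	SMN
r05-R	SMN
r06-L	SRN
r06-R	SRN
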