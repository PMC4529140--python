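region_label	group_label
r00-L	frontal
r00-R	frontal
r01-L	frontal
r01-R	frontal
r02-L	temporal
r02-R	temporal
r03-L	temporal
r03-R	temporal
r04-L	parietal
r04-R	parietal
r05-L	parietal
r05-R	parietal
r06-L	occipital
r06-R	occipital
r07-L	occipital
r07-R	occipital
r08-L	medial-temporal
r08-R	medial-temporal
r09-L	subcortical
r09-R	subcortical
r10-L	subcortical
r10-R	subcortical
r11-L	frontal
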