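gene	alteration	level
BRCA2	mutation	1
CDK4	amplification	2
ERBB2	amplification	1
ERBB2	mutation	2
IDH1	mutation	1
PIK3CA	mutation	1
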