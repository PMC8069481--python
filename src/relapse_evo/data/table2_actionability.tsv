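sample_id	lesion	biomarker	alteration	clone	ccf	classification
BC01	relapse	OncoKB	CDK4 amplification	Clone 1	1	Trunk
BC01	relapse	OncoKB	ERBB2 mutation	Clone 5	0.522	Branch
BC02	relapse	HRD	(HRD score >= 42)	NA	NA	NA
BC03	relapse	OncoKB	BRCA2 mutation	Clone 4	0.943	Branch
BC05	primary	OncoKB	PIK3CA mutation	Clone 1	1	Trunk
BC05	relapse	OncoKB	PIK3CA mutation	Clone 1	1	Trunk
BC05	relapse	OncoKB	IDH1 mutation	Clone 2	0.838	Branch
BC05	relapse	OncoKB	ERBB2 amplification	Clone 2	0.838	Branch
BC05	relapse	HRD	(HRD score >= 42)	NA	NA	NA
BC07	primary	HRD	Bi-allelic BRCA2	NA	NA	NA
BC07	relapse	HRD	Bi-allelic BRCA2	NA	NA	NA
BC09	primary	OncoKB	ERBB2 amplification	Clone 2	0.554	Branch
BC09	relapse	OncoKB	ERBB2 amplification	Clone 2	0.682	Branch
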