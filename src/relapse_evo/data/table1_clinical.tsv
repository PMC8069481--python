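patient_id	age	laterality	grade	tumor_size_mm	node_status	er	pr	her2	subtype	relapse_months
BC01	48	Right	1	15	-	+	+	-	Luminal A-like
BC02	70	Left		<1	-	-	-	+	HER2-enriched	6
BC03	39	Left	2	40	-	+	+	-	Luminal A-like	45
BC04	47	Left	2		-	+	+	+	Luminal B-like	61
BC05	70	Left	2	18	-	+	-	-	Luminal A-like	59
BC06	29	Right	1	47	-	+	+	-	Luminal A-like
BC07	36	Left	2	24	-	+	+	-	Luminal A-like
BC08	47	Right	2	13	-	-	-			24
BC09	72	Right	2	25	-	+	-			23
BC10	27	Right	2	32	-	-	-	-	Triple negative	107
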