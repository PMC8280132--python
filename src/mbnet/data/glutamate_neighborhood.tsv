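# compound_a	compound_b	enzyme_label
L-glutamate	2-oxoglutarate	GLUD1
L-glutamate	2-oxoglutarate	GLUD2
2-oxoglutaramate	2-oxoglutarate	NIT2
L-glutamate-5-semialdehyde	L-glutamate	ALDH4A1
L-glutamate	L-glutamine	GLS
L-glutamate	L-glutamine	GLS2
L-glutamate	L-glutamine	GLUL
L-glutamine	D-glucosamine-6-phosphate	GFPT1
L-glutamine	D-glucosamine-6-phosphate	GFPT2
L-glutamine	5-phosphoribosylamine	PPAT
L-glutamate	4-aminobutanoate	GAD1
4-aminobutanoate	succinate-semialdehyde	ABAT
2-oxoglutaramate	ammonia	NIT2
ammonia	carbamoyl-phosphate	CPS1
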