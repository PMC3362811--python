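locus	left_label	right_label
87	Unique sequence	SVA_B(1)
273	L1MA5A	SVA_B(2)
361	SVA_B(2)	Unique
432	SVA2(6)	Unique
574	SVA_A(1)	L1PA5
689	SVA_C(1)	ERVL-E-int
1505	SVA_D(2)	Unique sequence
1652	AluJr4	SVA_C(5)
2299	Simple repeat (TA)	SVA_D(1)
2335	AluSx1	SVA_D(3)
2493	SVA_A(4)	SVA_A(4)
2836	SVA_C(1)	Unique
2981	SVA_A(2)	AluSg4
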