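sensilla	orn_class	receptors	glomerulus	ap	bar	bab	rn	dac
at1	Or67d	Or67d	DA1	-	-	w	+	-
at2	Or23a	Or23a	DA3	+	-	+	-	-
at2	Or83c	Or83c	DC3	-	-	+	-	-
at3	Or2a	Or2a	DA4m	-	-	+	+	-
at3	Or19a/b	Or19a,Or19b	DC1	-	-	+	+	-
at3	Or43a	Or43a	DA4l	-	-	+	+	-
at4	Or47b	Or47b	VA1v	-	-	+	-	-
at4	Or88a	Or88a	VA1d	+	+	+	-	-
at4	Or65a/b/c	Or65a,Or65b,Or65c	DL3	+	-	-	-	-
ab1	Gr21a	Gr21a	V	-	-	-	-	-
ab1	Or92a	Or92a	VA2	-	-	-	-	+
ab1	Or10a/Gr10a	Or10a,Gr10a	DL1	-	-	+	-	+
ab1	Or42b	Or42b	DM1	-	-	-	-	+
ab2	Or59b	Or59b	DM4	+	-	-	-	-
ab2	Or85a	Or85a	DM5	-	-	-	-	-
ab3	Or22a/b	Or22a,Or22b	DM2	-	-	-	-	+
ab3	Or85b	Or85b	VM5d	-	-	+	-	-
ab4	Or7a	Or7a	DL5	+	-	-	-	-
ab4	Or56a/Or33a	Or56a,Or33a	DA2	-	-	+	-	-
ab5	Or47a	Or47a	DM3	-	-	-	+	-
ab5	Or82a	Or82a	VA6	-	-	+	+	-
ab6	Or49b	Or49b	VA5	-	-	+	-	-
ab7	Or67c	Or67c	VC4	-	-	w	+	+
ab7	Or98a	Or98a	VM5v	-	-	w	+	-
ab8	Or9a	Or9a	VM3	-	-	-	-	-
ab8	Or43b	Or43b	VM2	+	-	-	-	-
ab9	Or67b	Or67b	VA3	-	-	+	-	+
ab9	Or69aA/B	Or69aA,Or69aB	D	-	-	+	-	+
ab10	Or49a/Or85f	Or49a,Or85f	DL4	-	-	-	+	-
ab10	Or67a	Or67a	DM6	-	-	-	+	+
ac1	IR31a	IR31a	VL2p	+	-	+	+	-
ac1	IR92a/IR76b	IR92a,IR76b	VM1	-	-	+	+	-
ac1	IR75d	IR75d	VL1	-	+	+	+	+
ac1	VM6	-	VM6	-	-	+	+	-
ac2	IR75a	IR75a	DP1l	-	-	+	-	-
ac2	IR41a/IR76b	IR41a,IR76b	VC3m	-	-	+	-	-
ac2	IR75d	IR75d	VL1	-	+	+	-	+
ac3	IR75a/b/c	IR75a,IR75b,IR75c	DL2d	-	-	+	-	-
ac3	Or35a/IR76b	Or35a,IR76b	VC3l	-	-	-	-	-
ac4	IR84a	IR84a	VL2a	-	+	+	+	-
ac4	IR76a/IR76b	IR76a,IR76b	VM4	-	-	-	+	-
ac4	IR75d	IR75d	VL1	-	+	+	+	+
ai1	Or13a	Or13a	DC2	-	-	-	+	+
ai1	Or46aB	Or46aB	VA7m	-	-	+	+	+
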