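Gene	Strand	Location	Size(bp)	Intergenics Length	Anticodon	AminoAcids	StartCodon	StopCodon
*tRNA^Phe^*	+	1–68	68	0	GAA			
*12S rRNA*	+	69–1011	943	0				
*tRNA^Val^*	+	1012–1083	72	0	TAC			
*16S rRNA*	+	1084–2771	1688	0				
*tRNA^Leu^*	+	2772–2845	74	89	TAA			
*ND1*	+	2935–3909	975	3		324	ATG	TAA
*tRNA^Ile^*	+	3913–3981	69	−1	GAT			
*tRNA^Gln^*	−	3981–4051	71	−1	TTG			
*tRNA^Met^*	+	4051–4119	69	0	CAT			
*ND2*	+	4120–5165	1046	0		348	ATG	TA-
*tRNA^Trp^*	+	5166–5236	71	171	TCA			
*tRNA^Tyr^*	−	5408–5474	67	48	TGC			
*tRNA^Ala^*	−	5523–5591	69	1	GTT			
*tRNA^Asn^*	−	5593–5665	73	36	GCA			
*tRNA^Cys^*	−	5702–5767	66	46	GTA			
*COXI*	+	5814–7358	1545	6		514	GTG	TAA
*tRNA^Ser^*	−	7365–7435	71	3	TGA			
*tRNA^Asp^*	+	7439–7511	73	6	GTC			
*COXII*	+	7518–8208	691	0		230	ATG	T-
*tRNA^Lys^*	+	8209–8282	72	1	TTT			
*ATPase8*	+	8284–8451	168	−8		55	ATG	TAA
*ATPase6*	+	8442–9124	683	0		227	ATG	TA-
*COXIII*	+	9125–9909	785	0		261	ATG	TA-
*tRNA^Gly^*	+	9910–9982	71	0	TCC			
*ND3*	+	9983–10,331	349	0		116	ATG	T-
*tRNA^Arg^*	+	10,332–10,400	69	0	TCG			
*ND4L*	+	10,401–10,697	297	−7		98	ATG	TAA
*ND4*	+	10,691–12,072	1382	0		460	ATG	T-
*tRNA^His^*	+	12,073–12,141	69	0	GTG			
*tRNA^Ser^*	+	12,142–12,208	68	3	GCT			
*tRNA^Leu^*	+	12,212–12,284	73	0	TAG			
*ND5*	+	12,285–14,123	1839	−2		612	ATG	TAG
*ND6*	−	14,120–14,641	522	0		173	ATG	TAG
*tRNA^Glu^*	−	14,642–14,710	69	4	TTC			
*Cytb*	+	14,715–15,851	1137	3		378	ATG	AGA
*tRNA^Thr^*	+	15,855–15,926	72	−1	TGT			
*tRNA^Pro^*	−	15,926–15,995	70	0	TGG			
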