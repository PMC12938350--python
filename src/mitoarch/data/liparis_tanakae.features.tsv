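Gene	Strand	Location	Size(bp)	Intergenics Length	Anticodon	AminoAcids	Start Codon	StopCodon
*tRNA^Phe^*	+	1–68	68	0	GAA			
*12S rRNA*	+	69–1012	944	0				
*tRNA^Val^*	+	1013–1084	72	0	TAC			
*16S rRNA*	+	1085–2772	1688	0				
*tRNA^Leu^*	+	2773–2846	74	600	TAA			
*ND1*	+	3447–4421	975	3		324	ATG	TAA
*tRNA^Ile^*	+	4425–4493	69	−1	GAT			
*tRNA^Gln^*	−	4493–4563	71	−1	TTG			
*tRNA^Met^*	+	4563–4631	69	0	CAT			
*ND2*	+	4632–5677	1046	0		348	ATG	TA-
*tRNA^Trp^*	+	5678–5748	71	54	TCA			
*tRNA^Asn^*	−	5803–5875	73	36	GTT			
*tRNA^Cys^*	−	5912–5977	66	1	GCA			
*tRNA^Tyr^*	−	5979–6045	67	−4	GTA			
*tRNA^Ala^*	−	6042–6104	63	198	TGC			
*tRNA^Ala^*	−	6303–6371	69	160	TGC			
*COXI*	+	6532–8076	1545	6		514	GTG	TAA
*tRNA^Ser^*	−	8083–8153	71	3	TGA			
*tRNA^Asp^*	+	8157–8229	73	22	GTC			
*COXII*	+	8252–8942	691	0		230	ATG	T-
*tRNA^Lys^*	+	8943–9016	74	1	TTT			
*ATPase8*	+	9018–9185	168	−10		55	ATG	TAA
*ATPase6*	+	9176–9858	683	0		227	ATG	TA-
*COXIII*	+	9859–10,643	785	0		261	ATG	TA-
*tRNA^Gly^*	+	10,644–10,716	73	0	TCC			
*ND3*	+	10,717–11,065	349	0		116	ATG	T-
*tRNA^Arg^*	+	11,066–11,134	69	0	TCG			
*ND4L*	+	11,135–11,431	297	−7		98	ATG	TAA
*ND4*	+	11,425–12,805	1381	0		460	ATG	T-
*tRNA^His^*	+	12,806–12,874	69	0	GTG			
*tRNA^Ser^*	+	12,875–12,941	67	3	GCT			
*tRNA^Leu^*	+	12,945–13,017	73	0	TAG			
*ND5*	+	13,018–14,856	1839	−4		612	ATG	TAA
*ND6*	−	14,853–15,374	522	0		173	ATG	TAA
*tRNA^Glu^*	−	15,375–15,443	69	4	TTC			
*Cytb*	+	15,448–16,588	1141	0		380	ATG	T-
*tRNA^Thr^*	+	16,589–16,660	72	−1	TGT			
*tRNA^Pro^*	−	16,660–16,729	70	0	TGG			
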