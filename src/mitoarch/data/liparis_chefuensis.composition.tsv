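Region	T%	C%	A%	G%	AT%	GC Skew%	AT Skew%
PCGs	33.08	26.61	25.95	14.37	59.03	−0.29868	−0.12079
rRNA	22.77	24.74	33.26	19.23	56.03	−0.12531	0.18722
tRNA	28.41	20.21	29.57	21.82	57.98	0.03831	0.02001
Control region	31.94	13.71	43.25	11.10	75.19	−0.1052	0.15042
Genome	30.16	24.79	30.75	14.30	60.91	−0.26836	0.00969
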