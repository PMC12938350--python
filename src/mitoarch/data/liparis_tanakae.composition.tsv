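Region	T%	C%	A%	G%	AT%	GC Skew%	AT Skew%
PCGs	30.52	26.21	26.21	14.43	56.73	−0.28986	−0.07597
rRNA	22.72	24.32	32.48	20.48	55.20	−0.08571	0.17681
tRNA	28.00	20.27	29.17	22.56	57.17	0.05346	0.02047
Control region	36.29	20.40	42.78	0.53	79.07	−0.94935	0.08208
Genome	27.77	28.10	29.64	14.49	57.41	−0.31956	0.03257
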