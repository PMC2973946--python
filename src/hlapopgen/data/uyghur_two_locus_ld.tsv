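locus1	locus2	allele1	allele2	hf_percent	ald_percent	mld_percent	rld
A	B	0201	4006	0.96	0.84	0.84	1.0000
A	B	0205	5001	1.92	1.80	1.80	1.0000
A	B	2501	1801	0.96	0.92	0.92	1.0000
A	B	2301	4901	1.92	1.85	2.34	0.7920
A	B	3001	1302	2.88	2.74	3.70	0.7400
A	B	3604	1529	0.96	0.93	1.41	0.6612
A	B	3301	1402	1.92	1.65	2.60	0.6324
A	B	3301	4403	0.96	0.82	1.30	0.6324
A	B	1101	3503	1.92	1.54	2.49	0.6161
A	B	2402	3901	1.44	1.22	2.19	0.5581
A	B	2601	3801	1.92	1.74	3.19	0.5467
A	B	0101	3701	1.92	1.66	3.11	0.5349
A	B	3201	3501	2.40	2.11	4.04	0.5235
B	DRB1	2703	0401	0.96	0.91	0.91	1.0000
B	DRB1	5106	1502	0.96	0.91	0.91	1.0000
B	DRB1	1517	1302	0.96	0.91	0.91	1.0000
B	DRB1	1402	0102	2.40	2.32	2.80	0.8297
B	DRB1	3701	1001	1.92	1.84	2.32	0.7930
B	DRB1	0702	1501	3.37	2.99	3.96	0.7561
B	DRB1	4102	1303	1.44	1.41	1.88	0.7463
B	DRB1	5201	1502	2.40	2.23	3.19	0.6973
B	DRB1	0801	0301	2.40	2.14	3.11	0.6894
B	DRB1	1302	0701	2.83	2.20	3.22	0.6818
B	DRB1	1529	0403	0.96	0.93	1.41	0.6612
B	DRB1	4403	0701	0.96	0.73	1.20	0.6028
B	DRB1	5001	0701	4.14	3.12	5.23	0.5971
B	DRB1	4801	1301	1.44	1.30	2.27	0.5739
B	DRB1	5101	0404	1.44	1.25	2.21	0.5644
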