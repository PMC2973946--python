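locus	allele	percent
A	0101	7.69
A	0201	12.50
A	0202	0.48
A	0203	0.48
A	0205	1.92
A	0206	0.48
A	0211	0.48
A	0214	0.48
A	0222	0.48
A	0236	0.48
A	0301	10.10
A	0302	0.96
A	0306	0.48
A	1101	13.46
A	1106	0.48
A	1110	1.44
A	1119	0.96
A	2301	2.88
A	2402	9.13
A	2403	1.44
A	2404	0.48
A	2501	0.96
A	2601	5.29
A	2602	0.48
A	2613	0.96
A	2901	0.48
A	3001	3.85
A	3002	0.48
A	3101	1.44
A	3201	4.33
A	3301	9.62
A	3604	1.92
A	6601	0.48
A	6801	1.92
A	7401	0.48
B	0702	4.33
B	0705	0.48
B	0801	3.37
B	0803	0.48
B	0805	0.48
B	1301	1.92
B	1302	3.85
B	1402	2.88
B	1501	1.92
B	1502	0.96
B	1503	0.96
B	1505	0.48
B	1508	0.48
B	1517	0.96
B	1518	0.96
B	1529	1.44
B	1801	4.81
B	2703	0.96
B	2704	0.48
B	2707	0.96
B	3501	6.73
B	3502	0.96
B	3503	2.88
B	3508	1.44
B	3520	0.48
B	3701	3.37
B	3801	3.37
B	3901	2.41
B	4001	0.96
B	4006	0.96
B	4009	0.48
B	4101	0.96
B	4102	1.92
B	4402	2.41
B	4403	1.44
B	4501	0.48
B	4601	0.96
B	4801	2.41
B	4901	2.41
B	5001	6.25
B	5004	0.48
B	5101	8.17
B	5102	0.48
B	5106	0.96
B	5201	3.37
B	5204	0.48
B	5301	0.48
B	5401	1.92
B	5601	0.48
B	5701	1.92
B	5801	4.81
DRB1	0101	4.81
DRB1	0102	2.88
DRB1	0301	7.69
DRB1	0305	2.40
DRB1	0306	0.48
DRB1	0317	0.96
DRB1	0401	5.29
DRB1	0402	0.48
DRB1	0403	1.92
DRB1	0404	2.40
DRB1	0405	1.92
DRB1	0701	16.35
DRB1	0801	0.96
DRB1	0803	0.48
DRB1	0901	1.92
DRB1	1001	2.40
DRB1	1101	3.85
DRB1	1104	3.85
DRB1	1106	0.48
DRB1	1111	0.48
DRB1	1201	1.92
DRB1	1202	2.88
DRB1	1301	5.77
DRB1	1302	4.81
DRB1	1303	1.92
DRB1	1305	0.96
DRB1	1401	1.92
DRB1	1403	0.48
DRB1	1404	0.96
DRB1	1405	1.44
DRB1	1407	0.96
DRB1	1501	8.65
DRB1	1502	5.29
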