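locus	ho	he	pd	pic	ppe	hwe_p
A	0.9231	0.9135	0.9784	0.9181	0.8230	0.5785
B	0.9808	0.9681	0.9887	0.9624	0.9353	0.9696
DRB1	0.9519	0.9231	0.9784	0.9338	0.8428	0.4242
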