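tumor_id	age	sex	max_diameter_cm	ihc_phenotype	lineage_marker	deficiency	recurrent	n_recurrences	treatments
1	38	F	2.3	Silent GH adenoma	POU1F1	TSH	No	0	TSS
2	65	M	3.0	Gonadotropinoma	NR5A1	TSH, ACTH	Yes	6	TSS, XRT, CBG, TMZ
3	52	F	6.2	Silent PRL/ACTH adenoma	TBX19	TSH, ACTH	No	0	TSS, XRT, CBG
4	49	F	2.7	Gonadotropinoma	NR5A1	TSH	No	0	TSS
5	63	M	5.4	Gonadotropinoma	NR5A1	All	Yes	2	TSS, TC
6	58	F	4.4	Silent GH/PRL/LH/FSH/TSH/ACTH adenoma	NR5A1	TSH	Yes	2	TSS
7	73	F	3.3	Silent GH/PRL/LH/FSH adenoma	NR5A1	TSH, ACTH	No	0	TSS, XRT
8	66	F	2.6	Silent GH/PRL/LH/FSH/ACTH adenoma	NR5A1	None	No	0	TSS
9	60	M	5.6	Gonadotropinoma	NR5A1	All	No	0	TC
10	47	F	3.9	Gonadotropinoma	NR5A1	TSH	No	0	TSS
11	60	M	3.8	Gonadotropinoma	NR5A1	All	No	0	TSS
12	47	M	7.0	Gonadotropinoma	NR5A1	All	Yes	1	TC, CBG
13	45	F	3.5	Silent ACTH adenoma	TBX19	TSH	Yes	1	TSS
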