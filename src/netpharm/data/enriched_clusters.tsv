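term_id	category	description	count	percent	log10_p	log10_q
hsa05200	KEGG pathway	Pathways in cancer	17	65.38	-24.08	-19.76
GO:0048545	GO biological processes	Response to steroid hormone	14	53.85	-18.36	-14.34
GO:0010035	GO biological processes	Response to inorganic substance	15	57.69	-17.79	-14.07
hsa05161	KEGG pathway	Hepatitis B	11	42.31	-17.79	-14.07
hsa05212	KEGG pathway	Pancreatic cancer	8	30.77	-14.63	-11.16
GO:0051090	GO biological processes	Regulation of DNA binding transcription factor activity	12	46.15	-14.15	-10.84
GO:0048608	GO biological processes	Reproductive structure development	12	46.15	-14.15	-10.84
GO:0050673	GO biological processes	Epithelial cell proliferation	12	46.15	-13.98	-10.75
hsa04933	KEGG pathway	AGE-RAGE signalling pathway in diabetic complications	8	30.77	-13.06	-9.94
GO:0097190	GO biological processes	Apoptotic signalling pathway	12	46.15	-12.44	-9.45
M197	Canonical pathways	PID HIV NEF Pathway	6	23.08	-11.88	-8.97
hsa05224	KEGG pathway	Breast cancer	8	30.77	-11.73	-8.87
GO:0060749	GO biological processes	Mammary gland alveolus development	5	19.23	-11.09	-8.36
GO:0030099	GO biological processes	Myeloid cell differentiation	10	38.46	-11.05	-8.34
hsa04066	KEGG pathway	HIF-1 signalling pathway	7	26.92	-10.95	-8.27
GO:0009410	GO biological processes	Response to xenobiotic stimulus	9	34.62	-10.9	-8.22
R-HSA-6785807	Reactome gene sets	Interleukin-4 and Interleukin-13 signalling	7	26.92	-10.75	-8.1
GO:0009314	GO biological processes	Response to radiation	10	38.46	-10.74	-8.1
hsa05416	KEGG pathway	Viral myocarditis	6	23.08	-10.44	-7.85
GO:0051384	GO biological processes	Response to glucocorticoid	7	26.92	-9.82	-7.34
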