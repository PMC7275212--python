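symbol	gene_name	degree	closeness
IL-6	Interleukin-6	50	64.33333
CASP3	Caspase-3	48	63.33333
MAPK8	Mitogen-activated protein kinase 8	47	62.5
VEGF-A	Vascular endothelial growth factor A	47	62.5
EGFR	Epidermal growth factor receptor	46	62.16667
MYC	Myc protooncogene protein	45	61.5
ESR1	Estrogen receptor	44	61
CCND1	G1/S-specific cyclin-D1	42	60
FOS	Protooncogene c-Fos	38	58.5
ERBB2	Receptor tyrosine-protein kinase erbB-2	36	56.83333
AR	Androgen receptor	34	56
RELA	Transcription factor p65	32	55.5
PPARG	Peroxisome proliferator activated receptor gamma	32	55
NOS3	Nitric oxide synthase, endothelial	29	53.83333
PGR	Progesterone receptor	28	53
CASP8	Caspase-8	27	52
CAV1	Caveolin-1	26	51.5
AHR	Aryl hydrocarbon receptor	25	51.16667
ICAM1	Intercellular adhesion molecule 1	24	51
HIF-1A	Hypoxia-inducible factor 1-alpha	24	51
CASP9	Caspase-9	24	50.66667
RB1	Retinoblastoma-associated protein	22	49.66667
CYP3A4	Cytochrome P450 3A4	21	49.5
NFE2L2	Nuclear factor erythroid 2-related factor 2	21	49.33333
NFKBIA	NF-kappa-B inhibitor alpha	20	48.66667
NQO1	NAD(P)H dehydrogenase [quinone] 1	20	48.33333
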