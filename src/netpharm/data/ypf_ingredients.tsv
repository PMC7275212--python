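mol_id	name	ob	dl	herb
MOL000211	Mairin	55.38	0.78	Huangqi
MOL000239	Jaranol	50.83	0.29	Huangqi
MOL000296	Hederagenin	36.91	0.75	Huangqi
MOL000033	(3S,8S,9S,10R,13R,14S,17R)-10,13-Dimethyl-17-[(2R,5S)-5-propan-2-yloctan-2-yl]-2,3,4,7,8,9,11,12,14,15,16,17-dodecahydro-1H-cyclopenta[a]phenanthren-3-ol	36.23	0.78	Huangqi
MOL000354	Isorhamnetin	49.6	0.31	Huangqi
MOL000371	3,9-Di-O-methylnissolin	53.74	0.48	Huangqi
MOL000374	5'-Hydroxyiso-muronulatol-2',5'-di-O-glucoside	41.72	0.69	Huangqi
MOL000378	7-O-Methylisomucronulatol	74.69	0.3	Huangqi
MOL000379	9,10-Dimethoxypterocarpan-3-O-beta-D-glucoside	36.74	0.92	Huangqi
MOL000380	(6aR,11aR)-9,10-Dimethoxy-6a,11a-dihydro-6H-benzofurano[3,2-c]chromen-3-ol	64.26	0.42	Huangqi
MOL000392	Formononetin	69.67	0.21	Huangqi
MOL000398	Isoflavanone	109.99	0.3	Huangqi
MOL000417	Calycosin	47.75	0.24	Huangqi
MOL000422	Kaempferol	41.88	0.24	Huangqi
MOL000433	FA	68.96	0.71	Huangqi
MOL000438	(3R)-3-(2-Hydroxy-3,4-dimethoxyphenyl)chroman-7-ol	67.67	0.26	Huangqi
MOL000439	Isomucronulatol-7,2'-di-O-glucosiole	49.28	0.62	Huangqi
MOL000442	1,7-Dihydroxy-3,9-dimethoxy pterocarpene	39.05	0.48	Huangqi
MOL000098	Quercetin	46.43	0.28	Huangqi
MOL000011	(2R,3R)-3-(4-Hydroxy-3-methoxy-phenyl)-5-methoxy-2-methylol-2,3-dihydropyrano[5,6-h][1,4]benzodioxin-9-one	68.83	0.66	Fangfeng
MOL011730	11-Hydroxy-sec-o-beta-d-glucosylhamaudol_qt	50.24	0.27	Fangfeng
MOL011732	Anomalin	59.65	0.66	Fangfeng
MOL011737	Divaricatacid	87	0.32	Fangfeng
MOL001941	Ammidin	34.55	0.22	Fangfeng
MOL011749	Phelloptorin	43.39	0.28	Fangfeng
MOL011753	5-O-Methylvisamminol	37.99	0.25	Fangfeng
MOL002644	Phellopterin	40.19	0.28	Fangfeng
MOL000359	Sitosterol	36.91	0.75	Fangfeng
MOL000358	beta-Sitosterol	36.91	0.75	Fangfeng
MOL001494	Mandenol	42	0.19	Fangfeng
MOL001942	Isoimperatorin	45.46	0.23	Fangfeng
MOL003588	Prangenidin	36.31	0.22	Fangfeng
MOL007514	Methyl icosa-11,14-dienoate	39.67	0.23	Fangfeng
MOL013077	Decursin	39.27	0.38	Fangfeng
MOL000020	12-Senecioyl-2E,8E,10E-atractylentriol	62.4	0.22	Baizhu
MOL000021	14-Acetyl-12-senecioyl-2E,8E,10E-atractylentriol	60.31	0.31	Baizhu
MOL000022	14-Acetyl-12-senecioyl-2E,8Z,10E-atractylentriol	63.37	0.3	Baizhu
MOL000028	alpha-Amyrin	39.51	0.76	Baizhu
MOL000033	(3S,8S,9S,10R,13R,14S,17R)-10,13-Dimethyl-17-[(2R,5S)-5-propan-2-yloctan-2-yl]-2,3,4,7,8,9,11,12,14,15,16,17-dodecahydro-1H-cyclopenta[a]phenanthren-3-ol	36.23	0.78	Baizhu
MOL000049	3beta-Acetoxyatractylone	54.07	0.22	Baizhu
MOL000072	8beta-Ethoxy atractylenolide III	35.95	0.21	Baizhu
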