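compound_id	name	ob	dl	herbs
MOL000449	Stigmasterol	43.83	0.76	GRR,ASR,RRP
MOL004908	1,3-dihydroxy-8,9-dimethoxy-6-benzofurano[3,2-c]chromenone	62.9	0.53	RRG
MOL000358	ß-sitosterol	36.91	0.75	GRR,ASR,PRA
MOL004910	(2R)-7-hydroxy-2-(4-hydroxyphenyl)chroman-4-one	71.12	0.18	RRG
MOL003648	Inermin	65.83	0.54	GRR
MOL004911	Glabrene	46.27	0.44	RRG
MOL005317	Deoxyharringtonine	39.27	0.81	GRR
MOL004912	Glabrone	52.51	0.5	RRG
MOL005320	Arachidonate	45.57	0.2	GRR
MOL004913	Hedysarimcoumestan B	48.14	0.43	RRG
MOL005321	Frutinone A	65.9	0.34	GRR
MOL004914	Glabridin	53.25	0.47	RRG
MOL005356	Girinimbine	61.22	0.31	GRR
MOL004915	Eurycarpin A	43.28	0.37	RRG
MOL005376	Panaxadiol	33.09	0.79	GRR
MOL004924	(-)-Medicocarpin	40.99	0.95	RRG
MOL005384	Suchilactone	57.52	0.56	GRR
MOL004935	Sigmoidin B	34.88	0.41	RRG
MOL000787	Fumarine	59.26	0.83	GRR
MOL004941	Glabranin	52.9	0.31	RRG
MOL002879	Diop	43.59	0.39	GRR
MOL004945	Isobavachin	36.57	0.32	RRG
MOL000422	Kaempferol	41.88	0.24	GRR,PRA,RRG
MOL004948	Isoglycyrol	44.7	0.84	RRG
MOL005308	Aposiopolamine	66.65	0.22	GRR
MOL004949	Isolicoflavonol	45.17	0.42	RRG
MOL005344	Ginsenoside Rh2	36.32	0.56	GRR
MOL004957	Isoformononetin	38.37	0.21	RRG
MOL005348	Ginsenoside Rh4	31.11	0.78	GRR
MOL001484	Inermine	75.18	0.54	RRG
MOL005318	Dianthramine	40.45	0.2	GRR
MOL004959	1-Methoxyphaseollidin	69.98	0.64	RRG
MOL005399	Daucosterol	36.91	0.75	GRR
MOL004993	8-prenylated eriodictyol	53.79	0.4	RRG
MOL000676	Dibutyl Phthalate	64.54	0.13	GRR,PRA
MOL004961	Quercetin der.	46.45	0.33	RRG
MOL000273	(3ß,16α)-3,16-Dihydroxylanosta-7,9(11),24-trien-21-oic acid	30.93	0.81	P
MOL004966	7,2′,4′-trihydroxy-5-methoxy-3-arylcoumarin	83.71	0.27	RRG
MOL000275	Trametenolic acid	38.71	0.8	P
MOL000497	Licochalcone A	40.79	0.29	RRG
MOL000279	Cerevisterol	37.96	0.77	P
MOL004974	3′-Methoxyglabridin	46.16	0.57	RRG
MOL000282	Stellasterol	43.51	0.72	P
MOL004978	4′-Methoxyglabridin	36.21	0.52	RRG
MOL000283	Ergosterol peroxide	40.36	0.81	P
MOL004980	Inflacoumarin A	39.71	0.33	RRG
MOL000296	Hederagenin	36.91	0.75	P
MOL004985	Icos-5-enoic acid	30.7	0.2	RRG
MOL000022	14-acetyl-12-senecioyl-2E,8Z,10E-atractylentriol	63.37	0.3	AMR
MOL004988	Kanzonol F	32.47	0.89	RRG
MOL000033	(3S,8S,9S,10R,13R,14S,17R)-10,13-dimethyl-17-[(2R,5S)-5-propan-2-yloctan-2-yl]-2,3,4,7,8,9,11,12,14,15,16,17-dodecahydro-1H-cyclopenta[a]phenanthren-3-ol	36.23	0.78	AMR
MOL004989	(2S)-6-(2,4-dihydroxyphenyl)-2-(2-hydroxypropan-2-yl)-4-methoxy-2,3-dihydrofuro[3,2-g]chromen-7-one	60.25	0.63	RRG
MOL000049	3ß-acetoxyatractylone	54.07	0.22	AMR
MOL004990	3′-Hydroxy-4′-O-Methylglabridin	43.71	0.57	RRG
MOL000072	8ß-ethoxy atractylenolide III	35.95	0.21	AMR
MOL004991	7-Acetoxy-2-methylisoflavone	38.92	0.26	RRG
MOL001792	Liquiritigenin	32.76	0.18	RRG
MOL004996	Gadelaidic acid	30.7	0.2	RRG
MOL000211	Mairin	55.38	0.78	RRG,PRA
MOL000500	Vestitol	74.66	0.21	RRG
MOL002311	Glycyrol	90.78	0.67	RRG
MOL005000	Gancaonin G	60.44	0.39	RRG
MOL000239	Jaranol	50.83	0.29	RRG
MOL005001	Gancaonin H	50.1	0.78	RRG
MOL002565	Medicarpin	49.22	0.34	RRG
MOL005003	Licoagrocarpin	58.81	0.58	RRG
MOL000354	Isorhamnetin	49.6	0.31	RRG
MOL005007	Glyasperins M	72.67	0.59	RRG
MOL000359	Sitosterol	36.91	0.75	RRG,CR,RRP,PRA
MOL005008	Glycyrrhiza flavonol A	41.28	0.6	RRG
MOL003656	Lupiwighteone	51.64	0.37	RRG
MOL005012	Licoagroisoflavone	57.28	0.49	RRG
MOL003896	7-Methoxy-2-methyl isoflavone	42.56	0.2	RRG
MOL005016	Odoratin	49.95	0.3	RRG
MOL000392	Formononetin	69.67	0.21	RRG
MOL005017	Phaseol	78.77	0.58	RRG
MOL000417	Calycosin	47.75	0.24	RRG
MOL005018	Xambioona	54.85	0.87	RRG
MOL004328	Naringenin	59.29	0.21	RRG
MOL005020	Dehydroglyasperins C	53.82	0.37	RRG
MOL004805	Shinflavanone	31.79	0.72	RRG
MOL000098	Quercetin	46.43	0.28	RRG
MOL004806	Euchrenone	30.29	0.57	RRG
MOL000360	Ferulic acid	39.56	0.06	ASR,CR
MOL004808	Glyasperin B	65.22	0.44	RRG
MOL011782	Ligustilide	23.5	0.07	ASR,CR
MOL004810	Glyasperin F	75.84	0.54	RRG
MOL002143	Senkyunolide-C	46.8	0.08	ASR,CR
MOL004811	Glyasperin C	45.56	0.4	RRG
MOL002111	3-Butylidenephthalide	42.44	0.07	ASR,CR
MOL004814	Isotrifoliol	31.94	0.42	RRG
MOL001494	Mandenol	42	0.19	CR
MOL004815	Kanzonol B	39.62	0.35	RRG
MOL002135	Myricanone	40.6	0.51	CR
MOL004820	Kanzonol W	50.48	0.52	RRG
MOL002140	Perlolyrine	65.95	0.27	CR
MOL004824	6-prenylated eriodictyol	39.22	0.41	RRG
MOL002157	Wallichilide	42.31	0.71	CR
MOL004827	Semilicoisoflavone B	48.78	0.55	RRG
MOL000433	Folic Acid	68.96	0.71	CR
MOL004828	Glepidotin A	44.72	0.35	RRG
MOL001918	Paeoniflorigenone	87.59	0.37	PRA
MOL004829	Glepidotin B	64.46	0.34	RRG
MOL001919	Palbinone	43.56	0.53	PRA
MOL004833	Phaseolinisoflavan	32.01	0.45	RRG
MOL001924	paeoniflorin	53.87	0.79	PRA
MOL004835	Glypallichalcone	61.6	0.19	RRG
MOL000492	Cianidanol	54.83	0.24	PRA
MOL004838	Glabrocoumarone A	58.44	0.38	RRG
MOL000748	5-(Hydroxymethyl)-2-furaldehyde	45.07	0.02	RRP
MOL004841	Licochalcone B	76.76	0.19	RRG
MOL001436	Leonuride	2.6	0.33	RRP
MOL004848	Licochalcone G	49.25	0.32	RRG
MOL002819	Catalpol	5.07	0.44	RRP
MOL004849	Licoarylcoumarin	59.62	0.43	RRG
MOL000067	Valine	53.33	0.01	ACC
MOL004855	Licoricone	63.58	0.47	RRG
MOL007579	Hydroxyproline	83.55	0.02	ACC
MOL004856	Gancaonin A	51.08	0.4	RRG
MOL000061	Proline	77.57	0.01	ACC
MOL004857	Gancaonin B	48.79	0.45	RRG
MOL000050	Glycine	48.74	0	ACC
MOL004863	Gancaonin L	66.37	0.41	RRG
MOL000071	Histidine	53.18	0.03	ACC
MOL004864	Gancaonin M	30.49	0.41	RRG
MOL000054	Arginine	47.64	0.03	ACC
MOL004866	Gancaonin O	44.15	0.41	RRG
MOL003971	Threonine	73.52	0.01	ACC
MOL004879	Glycyrin	52.61	0.47	RRG
MOL003969	Serine	98.5	0.01	ACC
MOL004882	Licocoumarone	33.21	0.36	RRG
MOL000052	Glutamic Acid	6.66	0.02	ACC
MOL004883	Licoisoflavone	41.61	0.42	RRG
MOL000042	Alanine	87.69	0.01	ACC
MOL004884	Licoisoflavone B	38.93	0.55	RRG
MOL005449	Methionine	70.87	0.01	ACC
MOL004885	Licoisoflavanone	52.47	0.54	RRG
MOL005448	Leucine	72.92	0.01	ACC
MOL004891	Shinpterocarpin	80.3	0.73	RRG
MOL000068	Isoleucine	59.05	0.02	ACC
MOL004898	5-Prenylbutein	46.27	0.31	RRG
MOL000056	Tyrosine	57.55	0.05	ACC
MOL004903	Liquiritin	65.69	0.74	RRG
MOL000041	Phenylalanine	41.62	0.04	ACC
MOL004904	Licopyranocoumarin	80.36	0.65	RRG
MOL000065	Aspartic Acid	79.74	0.02	ACC
MOL004907	Glyzaglabrin	61.07	0.35	RRG
MOL001780	Tryptophane	75.93	0.08	ACC
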