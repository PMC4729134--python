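locus_id	chromosome	start	end	strand	new_flag	curated
Vitvi00g00586	chr00	13358491	13359102	+		0
Vitvi00g01439	chr00	23413171	23413974	+	v0	0
Vitvi00g00267	chr00	6600239	6600842	+	v0	0
Vitvi01g01424	chr01	18957579	18958217	-		1
Vitvi01g01831	chr01	19022801	19023439	-		1
Vitvi01g00008	chr01	150565	175325	-		0
Vitvi01g00011	chr01	194371	206245	-		0
Vitvi01g01673	chr01	22436834	22521665	-	v0	0
Vitvi01g01677	chr01	22565097	22582170	-		0
Vitvi01g00126	chr01	1353272	1355573	+		1
Vitvi02g01306	chr02	13242266	13243303	+	v0	0
Vitvi02g01303	chr02	13263986	13264774	+	v0	0
Vitvi02g00206	chr02	1905662	1906827	+		1
Vitvi02g00427	chr02	4010223	4021137	+		1
Vitvi03g00729	chr03	8696026	8696664	+		1
Vitvi03g00730	chr03	8744237	8744878	+		0
Vitvi03g00732	chr03	8776002	8776646	+		1
Vitvi03g00733	chr03	8793246	8793890	+		0
Vitvi03g00734	chr03	8820035	8820694	+		0
Vitvi03g01067	chr03	16246257	16246517	-	v1	0
Vitvi03g01317	chr03	16246670	16246942	-	v1	0
Vitvi03g01318	chr03	16247094	16247366	-	v0	0
Vitvi03g01320	chr03	12389395	12426843	-		0
Vitvi03g01059	chr03	16006264	16036390	-		0
Vitvi03g00819	chr03	10121969	10163135	+		0
Vitvi04g01016	chr04	14881133	14881462	-	v0	0
Vitvi04g00171	chr04	1588465	1591158	-		0
Vitvi04g01404	chr04	19762228	19764252	+	v1	0
Vitvi05g01725	chr05	8792525	8793580	+	v0	0
Vitvi05g01726	chr05	2819956	2820663	-	v0	0
Vitvi05g01728	chr05	2826143	2826844	-	v0	0
Vitvi05g01729	chr05	2828896	2829603	-	v0	0
Vitvi05g01727	chr05	2835002	2835637	-	v0	0
Vitvi05g01730	chr05	2823195	2823892	-	v0	0
Vitvi07g02071	chr07	12294351	12294983	+	v1	0
Vitvi07g02072	chr07	22189659	22189847	+		0
Vitvi07g01441	chr07	19961312	19968599	-		0
Vitvi07g01516	chr07	20841683	20858565	-		0
Vitvi07g01520	chr07	20874707	20895415	-		0
Vitvi07g01792	chr07	23583189	23586056	-		0
Vitvi08g01968	chr08	19810455	19810682	-	v0	0
Vitvi08g01967	chr08	4962832	4964430	-	v0	0
Vitvi08g01935	chr08	22162334	22164980	-		1
Vitvi10g00842	chr10	10291733	10292383	+		0
Vitvi10g01589	chr10	8229666	8230313	+	v0	0
Vitvi10g01588	chr10	8689978	8690526	+	v0	0
Vitvi10g01593	chr10	8694120	8694740	+	v0	0
Vitvi10g01592	chr10	6882283	6882954	-	v0	0
Vitvi10g01591	chr10	8703104	8703412	-	v0	0
Vitvi10g01590	chr10	8715924	8716592	-	v0	0
Vitvi10g01395	chr10	19893758	19899254	+		1
Vitvi10g00663	chr10	7289565	7297020	+		0
Vitvi12g00019	chr12	419028	430663	+		1
Vitvi13g01861	chr13	26016002	26024480	+		0
Vitvi14g00026	chr14	307222	307932	+		0
Vitvi14g01341	chr14	23320536	23341023	-		0
Vitvi14g01344	chr14	23363477	23379323	-		0
Vitvi14g01526	chr14	25510046	25535960	+		0
Vitvi15g01209	chr15	10201349	10202245	-	v0	0
Vitvi15g01212	chr15	13193733	13194680	+	v1	0
Vitvi15g01208	chr15	14612791	14614029	+	v0	0
Vitvi15g01211	chr15	13159995	13160894	-	v1	0
Vitvi15g01207	chr15	14586127	14587383	-	v0	0
Vitvi15g01213	chr15	4417318	4417578	-		0
Vitvi15g01210	chr15	10215314	10222523	-	v1	0
Vitvi15g00776	chr15	15406916	15424196	-		0
Vitvi15g00774	chr15	15375963	15398782	+		0
Vitvi15g01214	chr15	3906158	3907147	+		0
Vitvi15g00225	chr15	4852394	4882919	+		0
Vitvi16g00898	chr16	16506874	16543807	-		1
Vitvi16g00894	chr16	16451196	16466066	+		0
Vitvi17g01308	chr17	18151701	18152690	+	v0	0
Vitvi17g01307	chr17	9751998	9752990	+	v0	0
Vitvi17g01306	chr17	8039848	8040840	-	v0	0
Vitvi17g00470	chr17	5565954	5584339	-		0
Vitvi17g00471	chr17	5589790	5596034	-		0
Vitvi17g00098	chr17	1009821	1012257	+		1
Vitvi17g00614	chr17	7012571	7017470	+		0
Vitvi18g00221	chr18	2291990	2293992	-		1
Vitvi18g02133	chr18	30305897	30312249	-		1
Vitvi18g01044	chr18	11506619	11512146	+		0
Vitvi18g02145	chr18	30685886	30701598	+		0
Vitvi18g00361	chr18	4014840	4017395	+		1
Vitvi18g00517	chr18	5694915	5711044	+		0
Vitvi18g00553	chr18	6351256	6376057	+		0
Vitvi18g00700	chr18	7968590	7971054	+		0
Vitvi19g01487	chr19	19514486	19515085	+	v0	0
Vitvi19g01785	chr19	19540899	19541471	+	v0	0
Vitvi19g01491	chr19	19578381	19581226	-	v0	0
Vitvi19g00027	chr19	329777	330095	+		0
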