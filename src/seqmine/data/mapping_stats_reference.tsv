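dataset	sample	n_reads	n_unique	n_multi	n_failed	n_filtered	pct_mapped
mouse_set1	Mutant,_Control	22053527	14120075	2577992	5330066	25394	75.72
mouse_set1	Wild-type,_Control	29483443	19560525	3077978	6809626	35314	76.78
mouse_set1	Mutant,_CDDO	16050830	10500068	1832101	3699982	18679	76.83
mouse_set1	Wild-type,_CDDO	26643277	17185336	2840999	6585400	31542	75.16
mouse_set1	Mutant,_Sutherlandia	37321607	23776732	3690121	9813200	41554	73.60
mouse_set1	Wild-type,_Sutherlandia	27678509	18150349	2717683	6777541	32936	75.39
mouse_set1	Mutant,_Elderberry	25750508	17155488	2631750	5932836	30434	76.84
mouse_set1	Wild-type,_Elderberry	24036293	15882208	2386226	5738437	29422	76.00
mouse_set2	2A	12390167	9016108	1513122	1849425	11512	84.98
mouse_set2	2B	11760788	8220731	1445292	2083834	10931	82.19
mouse_set2	2C	9481395	6892027	1178753	1402253	8362	85.12
mouse_set2	2D	19450682	13849985	2406684	3176235	17778	83.58
mouse_set2	2E	11743452	8381763	1418645	1932480	10564	83.45
mouse_set2	2F	12104053	8692100	1510391	1890846	10716	84.29
mouse_set2	2G	13301646	9427606	1642257	2219819	11964	83.22
mouse_set2	2H	15766959	11158652	1950974	2643055	14278	83.15
mouse_set2	3A	22688673	16126579	2773025	3768846	20223	83.30
mouse_set2	3B	20352253	14506676	2503008	3324616	17953	83.58
mouse_set2	3C	20301445	14486410	2401849	3394815	18371	83.19
mouse_set2	3D	14985494	10729926	1876610	2365106	13852	84.12
drosophila_set3	CF1	51144998	45977130	900427	4241077	26364	91.66
drosophila_set3	CF2	81302211	74246307	1415608	5590921	49375	93.06
drosophila_set3	CF3	123512038	108573161	1797884	13075375	65618	89.36
drosophila_set3	CM1	77424855	70221478	1520820	5642533	40024	92.66
drosophila_set3	CM2	61946818	55327486	1103757	5477117	38458	91.10
drosophila_set3	CM3	69294584	61985415	1518519	5750241	40409	91.64
drosophila_set3	HMF1	85587833	78370743	1323717	5849024	44349	93.11
drosophila_set3	HMF2	44339865	39020383	701810	4593648	24024	89.59
drosophila_set3	HMF3	75974183	68654562	1302500	5973758	43363	92.08
drosophila_set3	HMM1	74429022	67318010	1682459	5382557	45996	92.71
drosophila_set3	HMM2	68985281	61450714	1302852	6195229	36486	90.97
drosophila_set3	HMM3	76796015	69056721	1578337	6116669	44288	91.98
drosophila_set4	CF1	83480611	56708379	2163167	24557803	51262	70.52
drosophila_set4	CF2	56660705	42714627	1398576	12513930	33572	77.86
drosophila_set4	CF3	67314472	50492765	1681644	15100773	39290	77.51
drosophila_set4	CM1	50000247	38470206	1206401	10291223	32417	79.35
drosophila_set4	CM2	70869571	53559942	1657406	15608111	44112	77.91
drosophila_set4	CM3	68530284	51799947	1627155	15061138	42044	77.96
drosophila_set4	mF1	78004841	61015420	2721937	14235541	31943	81.71
drosophila_set4	mF2	51629214	40273082	1573248	9745829	37055	81.05
drosophila_set4	mF3	75882842	59657154	2740131	13454327	31230	82.23
arabidopsis_set5	Col_1	27725818	24853210	973400	1897394	1814	93.15
arabidopsis_set5	Col_2	34323205	30712426	1319275	2289425	2079	93.32
arabidopsis_set5	Col_3	27486337	24759189	836816	1888591	1741	93.12
arabidopsis_set5	Col_1_qtrim	17555221	15965329	636099	953687	106	94.57
arabidopsis_set5	Col_2_qtrim	22064711	20041732	876453	1146446	80	94.80
arabidopsis_set5	Col_3_qtrim	17459673	15956994	548720	953897	62	94.54
arabidopsis_set5	hae-3_hsl2-3_1	26356053	23676670	886816	1790930	1637	93.20
arabidopsis_set5	hae-3_hsl2-3_2	20998406	18793308	727901	1475840	1357	92.97
arabidopsis_set5	hae-3_hsl2-3_3	28372647	25669013	914982	1786946	1706	93.70
arabidopsis_set5	hae-3_hsl2-3_1_qtrim	16641162	15168566	578226	894325	45	94.63
arabidopsis_set5	hae-3_hsl2-3_2_qtrim	13167066	11963242	473323	730435	66	94.45
arabidopsis_set5	hae-3_hsl2-3_3_qtrim	17927078	16467776	597035	862219	48	95.19
human_set6	1Sfesrrb-2	17448758	16392693	692905	363022	138	97.92
human_set6	1Sfesrrb-3	16228533	15239649	662064	326704	116	97.99
human_set6	2pc3-1	15582276	14641199	626397	314544	136	97.98
human_set6	2pc3-3	17066953	16009327	707445	350042	139	97.95
human_set6	3DY131-1	17130579	15966495	806969	357004	111	97.92
human_set6	3DY131-2	15500204	14623868	576060	300168	108	98.06
human_set6	4ctrl-1	19117412	17885236	858147	373922	107	98.04
human_set6	4ctrl-2	16269465	15280726	663813	324810	116	98.00
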