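plfa	Genus01	Genus02	Genus03	Genus04	Genus05	Genus06	Genus07	Genus08	Genus09	Genus10	Genus11	Genus12	Genus13	Genus14	Genus15	Genus16	Genus17	Genus18	Genus19	Genus20	Genus21	Genus22	Genus23	Genus24
i15:0	0.08628328048	0.01053544588	0.01053644483	0.1475529169	0.01238398765	0.294679167	0.01665821836	0.06677526352	0.008923006639	0.01288834265	0.004930535172	0.04573403964	0.07254292347	0.1488065516	0.09374013883	0.08937065406	0.03578397869	0.1139267394	0.2063728025	0.1522268511	0.08508790216	0.1271043322	0.01849322273	0.2057282894
a15:0	0.1209110742	0.1246826957	0.1087337351	0.01424477902	0.1298219512	0.04906162242	0.009497886472	0.0006355522963	0.2758383025	0.03414924138	0.195833926	0.0552107377	0.06133008089	0.02560156273	0.1686569333	0.09079090131	0.01460813513	0.01431804615	0.0532650765	0.06232703204	0.1057884675	0.0259859956	0.0968162384	0.101978088
15:0	0.003543089362	0.02796440438	0.07721230472	0.01326251116	0.04250650371	0.02824388685	0.03603832147	0.01054273233	0.04647241367	0.3501785199	0.1251084244	0.08154908337	0.1578458339	0.2600454215	0.001798451871	0.2454761243	0.03669002583	0.007672355107	0.00543210105	0.08231340564	0.00536090954	0.00522150462	0.005591540331	0.07543763477
i16:0	0.08237230755	0.04912043193	0.09723105368	0.05775211097	0.07207116741	0.1666004293	0.1879604035	0.009553695132	0.0006771449208	0.03028775479	0.07175944524	0.05470486351	0.07939581207	0.1670216054	0.1028320806	0.01366053553	0.01529751566	0.07812760082	0.05050702274	0.03342937773	0.03275754428	0.08527011096	0.4824732457	0.01529350689
16:0	0.005205269479	0.008498333867	0.0756694865	0.03205336512	0.004918178901	0.009209953761	0.04851042775	0.1276898838	0.1633493581	0.009600481	0.007225094741	0.02104017716	0.007962800206	0.09423823402	0.1248759836	0.01469441998	0.06160291162	0.1071479887	0.01197609488	0.04231697926	0.06799776014	0.1526051071	0.04650877941	0.008772444756
16:1w7	0.0210733319	0.01710623771	0.001591565219	0.04169229977	0.00203068639	0.006688032761	0.1142780057	0.017727423	0.01684566879	0.09737456986	0.04672987093	0.01322835588	0.005396362226	0.003951039685	0.1026283532	0.05301750763	0.0809047028	0.02146573335	0.02071268037	0.09513314317	0.3676070745	0.0628305254	0.1594574567	0.1220783259
10Me16:0	0.05521872295	0.04367486121	0.01801608962	0.009640230253	0.02822603582	0.02241016486	0.02843609506	0.137197681	0.07452051194	0.04845780657	0.03901776092	0.07185914695	0.04228896303	0.0513288364	0.09215698736	0.09703349088	0.02414181373	0.04849361663	0.06186744788	0.03318182724	0.08901594431	9.685881282e-05	0.005466443127	0.03619413761
cy17:0	0.0278580973	0.1069626155	0.2144720851	0.3181631301	0.006335158948	0.1154287433	0.1044090223	0.01046636326	0.0738062086	0.07268697277	0.07106879196	0.1043479977	0.1006782658	0.02340792791	0.1189576692	0.01095737471	0.05826089169	0.02083406478	0.06253980256	0.001203661135	0.02268337565	0.07551549786	0.002297638346	0.1331987327
18:1w7	0.0410499553	0.1733210223	0.003531286977	0.02696957024	0.01184520741	0.006623817665	0.2469691576	0.3398395599	0.03267861811	0.2456727135	0.007576895421	0.3177506892	0.2440247821	0.01225431263	0.009876120522	0.02810822473	0.07523707394	0.4305439457	0.02197945358	0.05099697775	0.001488980938	0.02910091878	0.0004328601873	0.120088477
18:1w9	0.1060112003	0.03613990507	0.02731397283	0.1802269602	0.07134700502	0.01716625529	0.006582272524	0.03044368894	0.08675377483	0.01689286247	0.03294869253	0.06709827016	0.02239583902	0.02240580775	0.03722452936	0.1198917861	0.05147636968	0.016515623	0.1015969369	0.08547297	0.03913329679	0.07409709117	0.05297447733	0.05572783269
18:2w6	0.08147711397	0.1007477739	0.07511958828	0.05843118882	0.07372172872	0.06492118716	0.00868832495	0.114947031	0.04427171072	0.0253312382	0.02714650335	0.1339195773	0.02758287839	0.1326111791	0.05671490285	0.06318232015	0.1992191968	0.06870059138	0.113219446	0.02511454895	0.03585336358	0.1442034546	0.02530326819	0.07530826613
18:3w3	0.2509919287	0.1452090387	0.1072623487	0.007486057171	0.351272031	0.1689874008	0.06357151079	0.02842720863	0.0172258949	0.04475503477	0.02292404765	0.01767760435	0.01035923743	0.003497415647	0.007114392103	0.05606170072	0.04988385117	0.05536606023	0.003639740643	0.09606238453	0.02944105056	0.1445594005	0.07887830851	0.04713032027
18:3w6	0.08769484249	0.1087549277	0.1822232556	0.05980702652	0.1417721934	0.02650000861	0.01184640478	0.001310185267	0.1551254773	0.008186785401	0.08288315451	0.005142286532	0.04544646949	0.04552609458	0.009344176561	0.02854860457	0.137382946	0.009724230553	0.07329832506	0.09189319999	0.003700242879	0.05659195216	0.01425996317	0.001401726779
cy19:0	0.03030978603	0.04728230622	0.001086782816	0.03271785385	0.05174816452	0.02347933031	0.1165539488	0.1044437318	0.003511908994	0.003537676728	0.2648468572	0.01073717047	0.1227497519	0.00930401092	0.07407928071	0.08920635532	0.1595105873	0.007163404203	0.2135930694	0.1483276415	0.1140840872	0.01681725026	0.0110465578	0.001662217142
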