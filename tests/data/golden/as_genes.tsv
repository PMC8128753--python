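gene_id	n_exons	entropy	arh	p_value	significant
G01	7	2.804364096	0.002990826239	0.4630738523	False
G02	5	2.319618097	0.002309997437	0.49500998	False
G03	7	2.80428578	0.003069141835	0.4550898204	False
G04	4	1.996815163	0.0031848371	0.253493014	False
G05	3	1.584300453	0.0006620481322	0.6946107784	False
G06	4	1.995146245	0.004853755042	0.1676646707	False
G07	8	2.998568085	0.001431915192	0.748502994	False
G08	8	2.992914901	0.007085099493	0.125748503	False
G09	7	2.803419256	0.003935666363	0.3453093812	False
G10	4	1.991704506	0.00829549436	0.06786427146	False
G11	6	2.578219232	0.006743268577	0.1137724551	False
G12	3	1.581009287	0.003953213814	0.2674650699	False
G13	4	1.997606199	0.002393800614	0.3373253493	False
G14	8	2.999231567	0.0007684329412	0.8942115768	False
G15	7	2.803527476	0.00382744636	0.3672654691	False
G16	4	1.999291375	0.000708625036	0.622754491	False
G17	8	2.892921326	0.1070786741	0.02794411178	True
G18	8	2.998650191	0.001349808927	0.7624750499	False
G19	4	1.995959283	0.004040717333	0.1996007984	False
G20	7	2.80601006	0.001344861796	0.7385229541	False
G21	4	1.993992911	0.006007089202	0.1317365269	False
G22	3	1.579361715	0.005600785596	0.1756487026	False
G23	4	1.99066211	0.009337890047	0.05189620758	False
G24	3	1.575752112	0.009210388646	0.08183632735	False
G25	7	2.80462701	0.002727912403	0.5069860279	False
G26	5	2.316936744	0.004991351218	0.249500998	False
G27	5	2.32161221	0.0003158847413	0.9461077844	False
G28	7	2.806629907	0.0007250155043	0.8882235529	False
G29	6	2.583611879	0.001350621483	0.6546906188	False
G30	3	1.584353451	0.000609049896	0.7105788423	False
G31	5	2.320957057	0.0009710377002	0.7644710579	False
G32	4	1.999965275	3.472543751e-05	0.9640718563	False
G33	7	2.805651741	0.001703181197	0.6666666667	False
G34	7	2.805210225	0.002144696576	0.6147704591	False
G35	6	2.583652758	0.001309743126	0.6626746507	False
G36	4	1.99484751	0.005152490298	0.1596806387	False
G37	4	1.998848914	0.001151086479	0.502994012	False
G38	7	2.799477025	0.007877897504	0.1037924152	False
G39	5	2.32120453	0.000723565257	0.8403193613	False
G40	3	1.580921043	0.004041457401	0.2654690619	False
G41	4	1.994510207	0.005489793183	0.1516966068	False
G42	8	2.997973516	0.002026484287	0.6407185629	False
G43	7	2.801705673	0.005649248737	0.2195608782	False
G44	3	1.584535389	0.0004271121374	0.7884231537	False
G45	7	2.803182425	0.004172496801	0.3233532934	False
G46	3	1.58370802	0.001254480985	0.5688622754	False
G47	7	2.802856529	0.004498393211	0.2874251497	False
G48	3	1.583665765	0.001296735654	0.5588822355	False
G49	3	1.584386539	0.0005759616983	0.7225548902	False
G50	7	2.805119214	0.002235708541	0.6007984032	False
G51	3	1.583082126	0.001880374467	0.4331337325	False
G52	8	2.998810093	0.001189907003	0.8063872255	False
G53	4	1.999833165	0.0001668354396	0.8463073852	False
G54	3	1.583315286	0.001647214729	0.4850299401	False
G55	5	2.142417121	0.179510974	0.0119760479	True
G56	5	2.314702307	0.007225788199	0.1337325349	False
G57	6	2.579568834	0.005393667157	0.1856287425	False
G58	8	2.994087464	0.00591253611	0.1856287425	False
G59	8	2.997344342	0.002655657788	0.5209580838	False
G60	3	1.568090423	0.01687207812	0.02794411178	True
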