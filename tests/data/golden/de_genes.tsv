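gene_id	mean_log2_NZO	mean_log2_C3H	log2_ratio	ratio	wilcoxon_p	bh_q	present_NZO	present_C3H	de_flag	direction
G06	2.328044219	3.229702447	0.9016582278	1.868212065	0.007936507937	0.05291005291	True	True	True	up_in_C3H
G15	3.281434471	4.239891657	0.9584571856	1.943230697	0.007936507937	0.05291005291	True	True	True	up_in_C3H
G19	5.215252618	6.114701275	0.8994486575	1.865352981	0.007936507937	0.05291005291	True	True	True	up_in_C3H
G23	1.693639683	0.683783038	-1.009856645	0.4965955899	0.007936507937	0.05291005291	True	True	True	up_in_NZO
G28	4.880978464	3.898725091	-0.9822533731	0.5061884966	0.007936507937	0.05291005291	True	True	True	up_in_NZO
G35	3.768916537	4.812837603	1.043921066	2.061823826	0.007936507937	0.05291005291	True	True	True	up_in_C3H
G40	4.006636209	2.886835819	-1.11980039	0.4601574879	0.007936507937	0.05291005291	True	True	True	up_in_NZO
G46	3.656661951	4.70174271	1.045080759	2.063481864	0.007936507937	0.05291005291	True	True	True	up_in_C3H
G55	4.99243647	5.121274519	0.1288380494	1.093412709	0.007936507937	0.05291005291	True	True	False	none
G43	5.712252222	5.533691251	-0.1785609712	0.8835838954	0.01587301587	0.09523809524	True	True	False	none
G01	5.877325899	5.648473878	-0.2288520203	0.8533136194	0.02380952381	0.1298701299	True	True	False	none
G14	4.207316377	4.048894225	-0.1584221515	0.8960044786	0.05555555556	0.253968254	True	True	False	none
G50	5.233376961	5.137662129	-0.09571483231	0.9358084544	0.05555555556	0.253968254	True	True	False	none
G31	2.449345787	2.351430312	-0.0979154746	0.9343820894	0.06349206349	0.253968254	True	True	False	none
G60	6.868915938	7.318981507	0.4500655693	1.366102344	0.06349206349	0.253968254	True	True	False	none
G08	5.11721087	5.017180937	-0.1000299329	0.9330136332	0.0873015873	0.2857142857	True	True	False	none
G22	5.838923306	5.692956599	-0.1459667069	0.9037735829	0.0873015873	0.2857142857	True	True	False	none
G07	-0.1331993716	-0.07795290334	0.05524646826	1.039036596	0.09523809524	0.2857142857	False	False	False	none
G48	4.186526104	4.101687117	-0.0848389871	0.9428897619	0.09523809524	0.2857142857	True	True	False	none
G53	4.443648476	4.308616694	-0.1350317821	0.910649772	0.09523809524	0.2857142857	True	True	False	none
G03	3.272715999	3.185965927	-0.08675007189	0.9416415775	0.2222222222	0.5555555556	True	True	False	none
G13	4.730389198	4.557774544	-0.1726146533	0.8872332552	0.2222222222	0.5555555556	True	True	False	none
G24	4.73856267	4.867509616	0.1289469459	1.093495244	0.2222222222	0.5555555556	True	True	False	none
G29	2.440463149	2.37332329	-0.06713985821	0.9545284754	0.2222222222	0.5555555556	True	True	False	none
G10	4.287671303	4.213459559	-0.07421174485	0.9498609612	0.2777777778	0.6403940887	True	True	False	none
G11	6.032781924	5.928123771	-0.104658153	0.9300252863	0.3095238095	0.6403940887	True	True	False	none
G37	2.678927669	2.789596655	0.1106689863	1.079728797	0.3095238095	0.6403940887	True	True	False	none
G41	4.34582372	4.392286639	0.04646291855	1.032729855	0.3095238095	0.6403940887	True	True	False	none
G49	0.1971806849	0.2539176161	0.05673693119	1.04011059	0.3095238095	0.6403940887	False	False	False	none
G59	1.748200511	1.696070295	-0.0521302156	0.9645111253	0.3492063492	0.6984126984	True	True	False	none
G25	2.5000138	2.464754331	-0.03525946918	0.9758562369	0.4126984127	0.7647907648	True	True	False	none
G34	2.658073363	2.680341313	0.02226794961	1.015554701	0.4206349206	0.7647907648	True	True	False	none
G57	3.32419814	3.399539397	0.075341257	1.053610229	0.4206349206	0.7647907648	True	True	False	none
G33	4.283160869	4.334618121	0.0514572523	1.036311163	0.5396825397	0.888030888	True	True	False	none
G16	0.1753729818	0.1139703449	-0.06140263689	0.9583319435	0.5476190476	0.888030888	False	False	False	none
G30	3.227146153	3.155889213	-0.07125694026	0.9518083788	0.5476190476	0.888030888	True	True	False	none
G58	4.235668579	4.186628371	-0.04904020838	0.9665791578	0.5476190476	0.888030888	True	True	False	none
G39	2.880067897	2.808121999	-0.07194589802	0.951353952	0.5714285714	0.9022556391	True	True	False	none
G27	5.472910664	5.426374689	-0.04653597494	0.9682584052	0.6349206349	0.9768009768	True	True	False	none
G02	5.441779252	5.504606908	0.06282765611	1.044510978	0.6904761905	0.9863945578	True	True	False	none
G09	5.275337196	5.248720207	-0.02661698929	0.9817196589	0.6904761905	0.9863945578	True	True	False	none
G18	3.729155418	3.710977386	-0.01817803272	0.9874789962	0.6904761905	0.9863945578	True	True	False	none
G04	5.073137307	5.031868316	-0.04126899076	0.9717997788	0.8412698413	1	True	True	False	none
G21	4.270172701	4.227737375	-0.04243532679	0.9710144521	0.8412698413	1	True	True	False	none
G42	3.423306199	3.402937075	-0.02036912388	0.9859804021	0.8412698413	1	True	True	False	none
G45	0.6592380609	0.6286237646	-0.0306142963	0.9790033514	0.8412698413	1	True	True	False	none
G12	4.00347699	4.002801639	-0.0006753505498	0.9995319922	0.8888888889	1	True	True	False	none
G32	-1.077559045	-1.061115233	0.01644381212	1.011463187	0.9523809524	1	False	False	False	none
G36	2.156218665	2.156776411	0.0005577465153	1.000386675	0.9682539683	1	True	True	False	none
G05	3.435288293	3.433130135	-0.002158157998	0.9985051972	1	1	True	True	False	none
G17	5.685256326	5.704717692	0.01946136545	1.013580986	1	1	True	True	False	none
G20	4.76564979	4.76600367	0.0003538796508	1.000245321	1	1	True	True	False	none
G26	4.63733094	4.639368166	0.002037226006	1.001413095	1	1	True	True	False	none
G38	4.638990237	4.630086591	-0.008903645478	0.9938474681	1	1	True	True	False	none
G44	3.174343412	3.193402458	0.01905904561	1.013298371	1	1	True	True	False	none
G47	5.314587165	5.31318557	-0.001401595158	0.99902896	1	1	True	True	False	none
G51	3.887173396	3.873350822	-0.01382257363	0.9904646743	1	1	True	True	False	none
G52	4.48243051	4.493325727	0.01089521679	1.007580577	1	1	True	True	False	none
G54	2.691723256	2.663152653	-0.02857060309	0.9803911709	1	1	True	True	False	none
G56	3.376541991	3.363278615	-0.01326337658	0.9908486587	1	1	True	True	False	none
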