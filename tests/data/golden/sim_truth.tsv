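gene_id	absent_flag	de_flag	true_log2_fc	as_flag	affected_exons	as_delta
G01	False	False	0	False		0
G02	False	False	0	False		0
G03	False	False	0	False		0
G04	False	False	0	False		0
G05	False	False	0	False		0
G06	False	True	1	False		0
G07	True	False	0	False		0
G08	False	False	0	False		0
G09	False	False	0	False		0
G10	False	False	0	False		0
G11	False	False	0	False		0
G12	False	False	0	False		0
G13	False	False	0	False		0
G14	False	False	0	False		0
G15	False	True	1	False		0
G16	True	False	0	False		0
G17	False	False	0	True	G17.E04	2
G18	False	False	0	False		0
G19	False	True	1	False		0
G20	False	False	0	False		0
G21	False	False	0	False		0
G22	False	False	0	False		0
G23	False	True	-1	False		0
G24	False	False	0	False		0
G25	False	False	0	False		0
G26	False	False	0	False		0
G27	False	False	0	False		0
G28	False	True	-1	False		0
G29	False	False	0	False		0
G30	False	False	0	False		0
G31	False	False	0	False		0
G32	True	False	0	False		0
G33	False	False	0	False		0
G34	False	False	0	False		0
G35	False	True	1	False		0
G36	False	False	0	False		0
G37	False	False	0	False		0
G38	False	False	0	False		0
G39	False	False	0	False		0
G40	False	True	-1	False		0
G41	False	False	0	False		0
G42	False	False	0	False		0
G43	False	False	0	False		0
G44	False	False	0	False		0
G45	False	False	0	False		0
G46	False	True	1	False		0
G47	False	False	0	False		0
G48	False	False	0	False		0
G49	True	False	0	False		0
G50	False	False	0	False		0
G51	False	False	0	False		0
G52	False	False	0	False		0
G53	False	False	0	False		0
G54	False	False	0	False		0
G55	False	False	0	True	G55.E04	2
G56	False	False	0	False		0
G57	False	False	0	False		0
G58	False	False	0	False		0
G59	False	False	0	False		0
G60	False	True	1	False		0
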