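gene_id	frac_above_NZO	present_NZO	frac_above_C3H	present_C3H
G01	1	True	1	True
G02	1	True	1	True
G03	1	True	1	True
G04	1	True	1	True
G05	1	True	1	True
G06	1	True	1	True
G07	0.04	False	0.05	False
G08	1	True	1	True
G09	1	True	1	True
G10	1	True	1	True
G11	1	True	1	True
G12	1	True	1	True
G13	1	True	1	True
G14	1	True	1	True
G15	1	True	1	True
G16	0.1272727273	False	0.1272727273	False
G17	1	True	1	True
G18	1	True	1	True
G19	1	True	1	True
G20	1	True	1	True
G21	1	True	1	True
G22	1	True	1	True
G23	1	True	0.56	True
G24	1	True	1	True
G25	1	True	1	True
G26	1	True	1	True
G27	1	True	1	True
G28	1	True	1	True
G29	1	True	1	True
G30	1	True	1	True
G31	1	True	1	True
G32	0	False	0.04444444444	False
G33	1	True	1	True
G34	1	True	1	True
G35	1	True	1	True
G36	1	True	1	True
G37	1	True	1	True
G38	1	True	1	True
G39	1	True	1	True
G40	1	True	1	True
G41	1	True	1	True
G42	1	True	1	True
G43	1	True	1	True
G44	1	True	1	True
G45	0.5764705882	True	0.5058823529	True
G46	1	True	1	True
G47	1	True	1	True
G48	1	True	1	True
G49	0.34	False	0.42	False
G50	1	True	1	True
G51	1	True	1	True
G52	1	True	1	True
G53	1	True	1	True
G54	1	True	1	True
G55	1	True	1	True
G56	1	True	1	True
G57	1	True	1	True
G58	1	True	1	True
G59	1	True	1	True
G60	1	True	1	True
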