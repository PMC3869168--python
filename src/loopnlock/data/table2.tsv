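# Folding-rate and core-size table for 43 two-state proteins (published survey transcription).
# Columns: protein_id = lowercase PDB code; residues = chain length L; contacts = number of
# residue-residue contacts (6 A heavy-atom cutoff, |i-j| >= 3); core_residues / core_contacts =
# size of the locks-plus-neighbours core; ln_kf = natural log of the experimental folding rate.
protein_id	residues	contacts	core_residues	core_contacts	ln_kf
1aey	58	221	31	110	2.09
1aps	98	426	53	213	-1.48
1ba5	53	171	22	65	5.91
1cis	66	272	33	128	3.87
1e0l	37	94	11	17	10.37
1e0m	37	101	13	29	8.85
1fex	59	207	22	58	8.19
1fkr	107	424	51	186	1.45
1g6p	66	260	21	59	6.30
1gab	53	189	17	44	12.7
1hdn	85	369	44	153	2.70
1idz	54	173	15	39	8.73
1imp	86	343	39	139	7.31
1k0s	151	613	63	250	7.44
1k8o	87	324	41	125	-0.71
1k9q	40	114	12	28	8.37
1l2y	20	42	6	7	12.4
1n88	96	398	51	219	2.02
1nti	86	364	35	139	6.96
1nyg	58	212	27	83	4.54
1o6x	81	271	22	54	6.63
1pba	81	293	23	65	6.80
1pks	76	325	46	191	-1.05
1pse	69	233	32	97	1.17
1rfa	78	307	27	85	8.36
1ryk	69	280	17	43	9.08
1srm	56	192	28	79	4.04
1ss1	60	234	21	65	11.48
1w4e	45	159	18	56	10.22
1w4j	51	170	18	53	12.25
1wiu	93	408	60	244	0.41
1yza	106	352	28	76	8.40
2ait	74	306	34	125	4.20
2ax5	99	350	51	157	2.58
2bth	45	146	15	39	11.78
2hqi	72	342	39	144	0.18
2jwt	54	191	13	16	10.53
2pdd	43	135	14	31	9.80
2ptl	62	245	36	108	4.10
2rpn	58	250	25	88	2.46
2vil	126	559	66	293	6.80
3gb1	56	201	23	72	6.30
3mef	69	242	24	73	5.30
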