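family	region	total_species	medicinal_species
Acanthaceae	NATIONAL	169	52
Achariaceae	NATIONAL	11	2
Amaranthaceae	NATIONAL	33	19
Amaryllidaceae	NATIONAL	29	10
Anacardiaceae	NATIONAL	61	23
Annonaceae	NATIONAL	162	66
Apiaceae	NATIONAL	25	14
Apocynaceae	NATIONAL	226	72
Araceae	NATIONAL	201	27
Araliaceae	NATIONAL	60	23
Arecaceae	NATIONAL	218	23
Aristolochiaceae	NATIONAL	22	5
Asparagaceae	NATIONAL	80	22
Aspleniaceae	NATIONAL	41	1
Asteraceae	NATIONAL	237	139
Athyriaceae	NATIONAL	40	1
Balsaminaceae	NATIONAL	66	3
Begoniaceae	NATIONAL	41	2
Bignoniaceae	NATIONAL	42	13
Boraginaceae	NATIONAL	28	7
Brassicaceae	NATIONAL	12	4
Burseraceae	NATIONAL	27	4
Cactaceae	NATIONAL	11	3
Campanulaceae	NATIONAL	21	5
Capparaceae	NATIONAL	35	11
Celastraceae	NATIONAL	55	11
Clusiaceae	NATIONAL	48	12
Combretaceae	NATIONAL	29	21
Commelinaceae	NATIONAL	40	12
Connaraceae	NATIONAL	15	10
Convolvulaceae	NATIONAL	114	25
Crassulaceae	NATIONAL	10	4
Cucurbitaceae	NATIONAL	44	27
Cycadaceae	NATIONAL	14	4
Cyperaceae	NATIONAL	254	15
Davalliaceae	NATIONAL	18	4
Dennstaedtiaceae	NATIONAL	18	3
Dilleniaceae	NATIONAL	14	10
Dioscoreaceae	NATIONAL	38	9
Dipterocarpaceae	NATIONAL	67	11
Dryopteridaceae	NATIONAL	62	1
Ebenaceae	NATIONAL	61	18
Elaeocarpaceae	NATIONAL	21	5
Ericaceae	NATIONAL	37	1
Euphorbiaceae	NATIONAL	226	69
Fagaceae	NATIONAL	121	6
Gentianaceae	NATIONAL	38	5
Gesneriaceae	NATIONAL	153	5
Gleicheniaceae	NATIONAL	10	1
Hypericaceae	NATIONAL	11	5
Icacinaceae	NATIONAL	12	1
Lamiaceae	NATIONAL	233	83
Lauraceae	NATIONAL	112	23
Lecythidaceae	NATIONAL	18	4
Leguminosae	NATIONAL	530	195
Linderniaceae	NATIONAL	38	10
Lindsaeaceae	NATIONAL	23	1
Loganiaceae	NATIONAL	19	6
Loranthaceae	NATIONAL	31	5
Lycopodiaceae	NATIONAL	10	3
Lythraceae	NATIONAL	32	11
Magnoliaceae	NATIONAL	32	3
Malpighiaceae	NATIONAL	23	3
Malvaceae	NATIONAL	172	63
Marantaceae	NATIONAL	22	6
Melastomataceae	NATIONAL	99	14
Meliaceae	NATIONAL	72	20
Menispermaceae	NATIONAL	44	25
Moraceae	NATIONAL	144	39
Musaceae	NATIONAL	13	6
Myristicaceae	NATIONAL	36	8
Myrtaceae	NATIONAL	121	18
Nepenthaceae	NATIONAL	12	2
Nephrolepidaceae	NATIONAL	10	2
Oleaceae	NATIONAL	76	13
Orchidaceae	NATIONAL	1099	32
Orobanchaceae	NATIONAL	20	5
Oxalidaceae	NATIONAL	11	7
Pandanaceae	NATIONAL	26	6
Passifloraceae	NATIONAL	16	5
Phyllanthaceae	NATIONAL	178	60
Piperaceae	NATIONAL	48	12
Plantaginaceae	NATIONAL	47	6
Poaceae	NATIONAL	524	52
Polygalaceae	NATIONAL	25	7
Polygonaceae	NATIONAL	32	18
Polypodiaceae	NATIONAL	128	13
Primulaceae	NATIONAL	115	22
Proteaceae	NATIONAL	13	4
Pteridaceae	NATIONAL	99	8
Putranjivaceae	NATIONAL	16	1
Ranunculaceae	NATIONAL	20	13
Rhamnaceae	NATIONAL	14	11
Rhizophoraceae	NATIONAL	17	2
Rosaceae	NATIONAL	57	14
Rubiaceae	NATIONAL	416	112
Rutaceae	NATIONAL	65	34
Salicaceae	NATIONAL	35	9
Santalaceae	NATIONAL	15	2
Sapindaceae	NATIONAL	45	18
Sapotaceae	NATIONAL	46	7
Selaginellaceae	NATIONAL	20	3
Smilacaceae	NATIONAL	29	10
Solanaceae	NATIONAL	47	22
Stemonaceae	NATIONAL	14	5
Styracaceae	NATIONAL	10	2
Symplocaceae	NATIONAL	17	1
Tectariaceae	NATIONAL	14	3
Theaceae	NATIONAL	11	2
Thymelaeaceae	NATIONAL	12	7
Urticaceae	NATIONAL	76	18
Verbenaceae	NATIONAL	13	5
Violaceae	NATIONAL	10	3
Vitaceae	NATIONAL	57	22
Zingiberaceae	NATIONAL	290	77
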