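family	ci_low	ci_high
Acanthaceae	0.2430	0.3811
Achariaceae	0.0549	0.4841
Amaranthaceae	0.4069	0.7281
Amaryllidaceae	0.1993	0.5281
Anacardiaceae	0.2660	0.5031
Annonaceae	0.3347	0.4845
Apiaceae	0.3691	0.7341
Apocynaceae	0.2613	0.3820
Araceae	0.0941	0.1885
Araliaceae	0.2707	0.5104
Arecaceae	0.0715	0.1534
Aristolochiaceae	0.1023	0.4370
Asparagaceae	0.1893	0.3819
Aspleniaceae	0.0058	0.1257
Asteraceae	0.5228	0.6474
Athyriaceae	0.0060	0.1286
Balsaminaceae	0.0165	0.1253
Begoniaceae	0.0150	0.1616
Bignoniaceae	0.1908	0.4613
Boraginaceae	0.1273	0.4354
Brassicaceae	0.1386	0.6143
Burseraceae	0.0606	0.3267
Cactaceae	0.0992	0.5719
Campanulaceae	0.1073	0.4537
Capparaceae	0.1856	0.4811
Celastraceae	0.1159	0.3243
Clusiaceae	0.1495	0.3887
Combretaceae	0.5411	0.8527
Commelinaceae	0.1808	0.4554
Connaraceae	0.4133	0.8480
Convolvulaceae	0.1533	0.3040
Crassulaceae	0.1675	0.6921
Cucurbitaceae	0.4654	0.7430
Cycadaceae	0.1182	0.5510
Cyperaceae	0.0363	0.0952
Davalliaceae	0.0915	0.4557
Dennstaedtiaceae	0.0605	0.3958
Dilleniaceae	0.4490	0.8818
Dioscoreaceae	0.1304	0.3933
Dipterocarpaceae	0.0947	0.2710
Dryopteridaceae	0.0039	0.0853
Ebenaceae	0.1956	0.4195
Elaeocarpaceae	0.1073	0.4537
Ericaceae	0.0064	0.1381
Euphorbiaceae	0.2489	0.3683
Fagaceae	0.0234	0.1040
Gentianaceae	0.0586	0.2743
Gesneriaceae	0.0144	0.0741
Gleicheniaceae	0.0228	0.4128
Hypericaceae	0.2109	0.7233
Icacinaceae	0.0192	0.3603
Lamiaceae	0.2975	0.4197
Lauraceae	0.1411	0.2896
Lecythidaceae	0.0915	0.4557
Leguminosae	0.3280	0.4098
Linderniaceae	0.1500	0.4213
Lindsaeaceae	0.0103	0.2112
Loganiaceae	0.1539	0.5428
Loranthaceae	0.0721	0.3279
Lycopodiaceae	0.1093	0.6097
Lythraceae	0.2040	0.5183
Magnoliaceae	0.0340	0.2433
Malpighiaceae	0.0474	0.3236
Malvaceae	0.2979	0.4406
Marantaceae	0.1321	0.4841
Melastomataceae	0.0865	0.2237
Meliaceae	0.1877	0.3909
Menispermaceae	0.4215	0.7036
Moraceae	0.2050	0.3489
Musaceae	0.2304	0.7114
Myristicaceae	0.1177	0.3821
Myrtaceae	0.0964	0.2231
Nepenthaceae	0.0504	0.4545
Nephrolepidaceae	0.0602	0.5178
Oleaceae	0.1031	0.2714
Orchidaceae	0.0207	0.0408
Orobanchaceae	0.1128	0.4717
Oxalidaceae	0.3489	0.8483
Pandanaceae	0.1111	0.4226
Passifloraceae	0.1421	0.5596
Phyllanthaceae	0.2717	0.4094
Piperaceae	0.1495	0.3887
Plantaginaceae	0.0607	0.2525
Poaceae	0.0765	0.1279
Polygalaceae	0.1433	0.4779
Polygonaceae	0.3921	0.7189
Polypodiaceae	0.0606	0.1662
Primulaceae	0.1300	0.2729
Proteaceae	0.1276	0.5810
Pteridaceae	0.0420	0.1516
Putranjivaceae	0.0146	0.2869
Ranunculaceae	0.4303	0.8189
Rhamnaceae	0.5191	0.9221
Rhizophoraceae	0.0358	0.3471
Rosaceae	0.1526	0.3717
Rubiaceae	0.2289	0.3139
Rutaceae	0.4034	0.6401
Salicaceae	0.1420	0.4220
Santalaceae	0.0405	0.3835
Sapindaceae	0.2699	0.5463
Sapotaceae	0.0765	0.2831
Selaginellaceae	0.0545	0.3634
Smilacaceae	0.1993	0.5281
Solanaceae	0.3329	0.6083
Stemonaceae	0.1634	0.6162
Styracaceae	0.0602	0.5178
Symplocaceae	0.0138	0.2729
Tectariaceae	0.0779	0.4809
Theaceae	0.0549	0.4841
Thymelaeaceae	0.3158	0.8078
Urticaceae	0.1556	0.3441
Verbenaceae	0.1766	0.6486
Violaceae	0.1093	0.6097
Vitaceae	0.2704	0.5163
Zingiberaceae	0.2180	0.3192
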