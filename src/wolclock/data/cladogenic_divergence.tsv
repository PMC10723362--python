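pair	genome	d_third	d_syn	bp
Nasonia_longicornis_giraulti	wolbachia	0.2	0.3	4486
Nasonia_longicornis_giraulti	nuclear	NA	1.12	4135
Nasonia_longicornis_giraulti	mtdna	NA	45.24	2241
Drosophila_bicornuta_barbarae	wolbachia	2.4	3.7	620685
Drosophila_bicornuta_barbarae	nuclear	12.3	19.3	37401
Drosophila_bicornuta_barbarae	mtdna	15.7	28.0	11030
Brugia_malayi_pahangi	wolbachia	0.88	1.4	598257
Brugia_malayi_pahangi	nuclear	1.94	3.10	33099
Brugia_malayi_pahangi	mtdna	28.2	43.7	10361
Nomada_ferruginata_panzeri	wolbachia	0.29	0.46	613605
Nomada_ferruginata_panzeri	nuclear	1.73	2.39	36402
Nomada_ferruginata_panzeri	mtdna	2.53	4.95	9249
Nomada_ferruginata_flava	wolbachia	0.27	0.43	613605
Nomada_ferruginata_flava	nuclear	1.43	2.15	36402
Nomada_ferruginata_flava	mtdna	2.61	5.27	9249
Nomada_ferruginata_leucophtalma	wolbachia	0.27	0.43	613605
Nomada_ferruginata_leucophtalma	nuclear	1.47	2.13	36402
Nomada_ferruginata_leucophtalma	mtdna	2.22	4.45	9249
Nomada_panzeri_flava	wolbachia	0.032	0.051	613605
Nomada_panzeri_flava	nuclear	0.99	1.29	36402
Nomada_panzeri_flava	mtdna	2.42	4.94	9249
Nomada_panzeri_leucophtalma	wolbachia	0.033	0.051	613605
Nomada_panzeri_leucophtalma	nuclear	1.00	1.27	36402
Nomada_panzeri_leucophtalma	mtdna	2.25	4.52	9249
Nomada_flava_leucophtalma	wolbachia	0.0088	0.011	613605
Nomada_flava_leucophtalma	nuclear	0.65	1.06	36402
Nomada_flava_leucophtalma	mtdna	1.34	2.62	9249
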