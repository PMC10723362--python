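name	d_third_percent	d_syn_percent	T_years	T_low	T_high	group
Nasonia_longicornis_giraulti	0.2	0.3	460000	NA	NA	nasonia
Drosophila_bicornuta_barbarae	2.4	3.7	5500000	4650000	6350000	drosophila
Nomada_ferruginata_panzeri	0.29	0.46	2420000	1160000	3370000	nomada
Nomada_ferruginata_flava	0.27	0.43	2420000	1160000	3370000	nomada
Nomada_ferruginata_leucophtalma	0.27	0.43	2420000	1160000	3370000	nomada
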