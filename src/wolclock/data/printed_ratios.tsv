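pair	numerator	denominator	kind	printed
Nasonia_longicornis_giraulti	wolbachia	nuclear	third	NA
Nasonia_longicornis_giraulti	wolbachia	nuclear	synonymous	0.27
Nasonia_longicornis_giraulti	mtdna	wolbachia	third	NA
Nasonia_longicornis_giraulti	mtdna	wolbachia	synonymous	150.8
Nasonia_longicornis_giraulti	mtdna	nuclear	third	NA
Nasonia_longicornis_giraulti	mtdna	nuclear	synonymous	40.4
Drosophila_bicornuta_barbarae	wolbachia	nuclear	third	0.20
Drosophila_bicornuta_barbarae	wolbachia	nuclear	synonymous	0.19
Drosophila_bicornuta_barbarae	mtdna	wolbachia	third	6.54
Drosophila_bicornuta_barbarae	mtdna	wolbachia	synonymous	7.57
Drosophila_bicornuta_barbarae	mtdna	nuclear	third	1.28
Drosophila_bicornuta_barbarae	mtdna	nuclear	synonymous	1.45
Brugia_malayi_pahangi	wolbachia	nuclear	third	0.45
Brugia_malayi_pahangi	wolbachia	nuclear	synonymous	0.45
Brugia_malayi_pahangi	mtdna	wolbachia	third	32.0
Brugia_malayi_pahangi	mtdna	wolbachia	synonymous	31.2
Brugia_malayi_pahangi	mtdna	nuclear	third	14.5
Brugia_malayi_pahangi	mtdna	nuclear	synonymous	14.1
Nomada_ferruginata_panzeri	wolbachia	nuclear	third	0.17
Nomada_ferruginata_panzeri	wolbachia	nuclear	synonymous	0.19
Nomada_ferruginata_panzeri	mtdna	wolbachia	third	8.72
Nomada_ferruginata_panzeri	mtdna	wolbachia	synonymous	10.76
Nomada_ferruginata_panzeri	mtdna	nuclear	third	1.46
Nomada_ferruginata_panzeri	mtdna	nuclear	synonymous	2.07
Nomada_ferruginata_flava	wolbachia	nuclear	third	0.19
Nomada_ferruginata_flava	wolbachia	nuclear	synonymous	0.20
Nomada_ferruginata_flava	mtdna	wolbachia	third	9.67
Nomada_ferruginata_flava	mtdna	wolbachia	synonymous	12.26
Nomada_ferruginata_flava	mtdna	nuclear	third	1.83
Nomada_ferruginata_flava	mtdna	nuclear	synonymous	2.45
Nomada_ferruginata_leucophtalma	wolbachia	nuclear	third	0.18
Nomada_ferruginata_leucophtalma	wolbachia	nuclear	synonymous	0.20
Nomada_ferruginata_leucophtalma	mtdna	wolbachia	third	8.22
Nomada_ferruginata_leucophtalma	mtdna	wolbachia	synonymous	10.35
Nomada_ferruginata_leucophtalma	mtdna	nuclear	third	1.51
Nomada_ferruginata_leucophtalma	mtdna	nuclear	synonymous	2.09
Nomada_panzeri_flava	wolbachia	nuclear	third	0.032
Nomada_panzeri_flava	wolbachia	nuclear	synonymous	0.040
Nomada_panzeri_flava	mtdna	wolbachia	third	75.6
Nomada_panzeri_flava	mtdna	wolbachia	synonymous	96.9
Nomada_panzeri_flava	mtdna	nuclear	third	2.44
Nomada_panzeri_flava	mtdna	nuclear	synonymous	3.83
Nomada_panzeri_leucophtalma	wolbachia	nuclear	third	0.033
Nomada_panzeri_leucophtalma	wolbachia	nuclear	synonymous	0.040
Nomada_panzeri_leucophtalma	mtdna	wolbachia	third	68.2
Nomada_panzeri_leucophtalma	mtdna	wolbachia	synonymous	88.6
Nomada_panzeri_leucophtalma	mtdna	nuclear	third	2.25
Nomada_panzeri_leucophtalma	mtdna	nuclear	synonymous	3.56
Nomada_flava_leucophtalma	wolbachia	nuclear	third	0.014
Nomada_flava_leucophtalma	wolbachia	nuclear	synonymous	0.010
Nomada_flava_leucophtalma	mtdna	wolbachia	third	152.3
Nomada_flava_leucophtalma	mtdna	wolbachia	synonymous	238.2
Nomada_flava_leucophtalma	mtdna	nuclear	third	2.06
Nomada_flava_leucophtalma	mtdna	nuclear	synonymous	2.47
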