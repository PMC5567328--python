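class	nb_occ_millions	species_thousands	med_sp	mad	precision
Aves	345.11	12.82	371	541	0.99
Magnoliopsida	118.21	261.01	19	25	0.92
Insecta	46.78	352.78	3	3	0.77
Liliopsida	36.75	68.99	15	19	0.95
Actinopterygii	14.18	30.73	27	37	0.92
Mammalia	10.78	11.53	15	21	0.88
Bryopsida	6.06	18.85	7	9	0.95
Gastropoda	5.85	46.99	7	9	0.69
Reptilia	4.98	11.30	24	34	0.88
Lecanoromycetes	4.97	17.79	8	10	0.93
Polypodiopsida	4.91	12.65	23	31	0.95
Amphibia	3.94	5.89	54	76	0.91
Agaricomycetes	3.80	23.53	4	4	0.93
Malacostraca	2.73	30.16	6	7	0.73
Globothalamea	2.68	4.07	10	13	0.74
Arachnida	2.17	38.11	3	3	0.77
Bivalvia	2.02	14.02	9	12	0.70
Bacillariophyceae	1.96	11.19	2	1	0.70
Maxillopoda	1.87	9.98	4	4	0.58
Pinopsida	1.57	0.91	110	160	0.95
Jungermanniopsida	1.41	6.93	7	9	0.91
Polychaeta	1.29	8.77	6	7	0.73
Florideophyceae	1.07	5.78	17	24	0.88
Anthozoa	1.03	8.64	7	9	0.59
TOTAL_24_CLASSES	626.13	1013.39	7	9	0.94
TOTAL_GBIF	649.79	1200.38	6	7	0.93
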