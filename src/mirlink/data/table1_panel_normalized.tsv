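mirna_id	fc_q_vs_a	p_value	n_targets
miR-200b	22.55	0.0006	45
miR-200a	12.8	0.0029	38
miR-548b-5p	10.03	0.0068	35
miR-223	5643.5	2.06e-05	32
miR-489	50.55	0.008	31
miR-363	20.82	0.0025	29
miR-142-3p	941.7	0.0002	28
miR-192	8.53	0.0107	28
miR-135a	11.09	0.0031	27
miR-126	32.08	0.0098	23
miR-142-5p	387.72	0.001	23
miR-202	91.63	0.0218	23
miR-628-5p	14.28	0.0113	23
miR-375	153.42	0.0006	21
miR-522	17.14	0.0143	21
miR-150	870	0.0001	20
miR-429	27.76	0.0493	20
miR-126*	64.65	0.004	19
miR-885-5p	780.16	4.34e-06	19
miR-139-3p	33.47	0.0029	16
miR-302c*	32.21	0.0238	16
miR-139-5p	63.82	0.0069	15
miR-605	12.08	0.0127	15
miR-372	100.85	0.0149	12
miR-342-5p	17.53	0.0007	10
miR-520d-3p	8.37	0.0271	9
miR-572	26.23	0.0069	9
miR-483-5p	259.55	0.0023	8
miR-504	120.82	0.0011	8
miR-639	16.27	0.0197	8
miR-519a	15.4	0.0381	7
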