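# Caspase-2 saturation-mutagenesis reference dataset: one-step-perturbation
# free energies (kJ/mol) and contributing-frame percentages for the E105 and
# G171 sites, per reference-state variant (RDR, R2R) and P1' substrate residue.
# HisA: Nd1-H tautomer; HisB: Ne2-H tautomer.
site	p1prime	mutation	variant	p_contr	osp_dG
105	Ile	Ala	RDR	89.7	-16.2
105	Ile	Ala	R2R	28.52	1.0
105	Ile	Arg	RDR	0.52	110.2
105	Ile	Arg	R2R	16.15	-1.9
105	Ile	Asn	RDR	26.99	-5.1
105	Ile	Asn	R2R	11.18	3.4
105	Ile	Asp	RDR	30.38	-4.2
105	Ile	Asp	R2R	11.77	-4.6
105	Ile	Cys	RDR	0.89	-10.5
105	Ile	Cys	R2R	2.84	-16.3
105	Ile	Gly	RDR	2.11	-1.8
105	Ile	Gly	R2R	1.66	-6.9
105	Ile	Gln	RDR	1.08	6.0
105	Ile	Gln	R2R	5.81	6.6
105	Ile	Glu	RDR	17.99	-6.0
105	Ile	Glu	R2R	17.97	-1.2
105	Ile	HisA	RDR	1.23	-24.3
105	Ile	HisA	R2R	6.03	-8.8
105	Ile	HisB	RDR	0.84	-4.2
105	Ile	HisB	R2R	5.51	-7.0
105	Ile	Ile	RDR	2.75	-14.7
105	Ile	Ile	R2R	3.00	-1.2
105	Ile	Leu	RDR	4.97	-7.0
105	Ile	Leu	R2R	1.02	2.2
105	Ile	Lys	RDR	0.25	-5.8
105	Ile	Lys	R2R	1.45	0.3
105	Ile	Met	RDR	0.59	-20.7
105	Ile	Met	R2R	5.18	2.4
105	Ile	Phe	RDR	0.35	44.5
105	Ile	Phe	R2R	0.98	10.2
105	Ile	Ser	RDR	65.53	3.7
105	Ile	Ser	R2R	16.27	-12.6
105	Ile	Thr	RDR	26.89	-2.2
105	Ile	Thr	R2R	16.59	-2.6
105	Ile	Trp	RDR	0.45	-79.2
105	Ile	Trp	R2R	0.30	67.2
105	Ile	Tyr	RDR	0.56	-9.1
105	Ile	Tyr	R2R	0.37	6.9
105	Ile	Val	RDR	11.52	-1.2
105	Ile	Val	R2R	8.14	-1.2
105	Pro	Ala	RDR	76.64	-9.9
105	Pro	Ala	R2R	25.70	-8.5
105	Pro	Arg	RDR	0.60	162.3
105	Pro	Arg	R2R	18.84	-20.0
105	Pro	Asn	RDR	8.47	-0.3
105	Pro	Asn	R2R	10.91	-11.8
105	Pro	Asp	RDR	10.44	2.7
105	Pro	Asp	R2R	8.06	4.0
105	Pro	Cys	RDR	0.78	4.0
105	Pro	Cys	R2R	6.13	0.6
105	Pro	Gly	RDR	1.74	0.1
105	Pro	Gly	R2R	0.99	6.5
105	Pro	Gln	RDR	0.45	4.3
105	Pro	Gln	R2R	6.03	14.6
105	Pro	Glu	RDR	7.49	7.7
105	Pro	Glu	R2R	19.62	5.6
105	Pro	HisA	RDR	5.28	15.0
105	Pro	HisA	R2R	17.22	-5.1
105	Pro	HisB	RDR	16.48	-2.0
105	Pro	HisB	R2R	19.60	-8.4
105	Pro	Ile	RDR	0.78	-7.2
105	Pro	Ile	R2R	3.13	3.0
105	Pro	Leu	RDR	4.37	-1.4
105	Pro	Leu	R2R	0.67	16.2
105	Pro	Lys	RDR	0.67	-69.4
105	Pro	Lys	R2R	8.21	-4.1
105	Pro	Met	RDR	1.00	-16.1
105	Pro	Met	R2R	7.58	-15.2
105	Pro	Phe	RDR	0.39	36.0
105	Pro	Phe	R2R	8.43	-5.1
105	Pro	Ser	RDR	31.17	2.8
105	Pro	Ser	R2R	10.00	8.0
105	Pro	Thr	RDR	14.64	6.2
105	Pro	Thr	R2R	3.22	3.3
105	Pro	Trp	RDR	0.47	-187.3
105	Pro	Trp	R2R	4.55	-21.7
105	Pro	Tyr	RDR	0.45	485.5
105	Pro	Tyr	R2R	1.91	12.0
105	Pro	Val	RDR	6.51	2.3
105	Pro	Val	R2R	13.28	-3.1
171	Ile	Ala	RDR	64.84	-10.6
171	Ile	Ala	R2R	4.78	-6.4
171	Ile	Arg	RDR	0.31	5.2
171	Ile	Arg	R2R	2.11	-2.0
171	Ile	Asn	RDR	28.96	4.0
171	Ile	Asn	R2R	11.41	1.5
171	Ile	Asp	RDR	26.68	-12.9
171	Ile	Asp	R2R	12.18	-5.1
171	Ile	Cys	RDR	1.13	-4.3
171	Ile	Cys	R2R	1.89	2.3
171	Ile	Gly	RDR	8.45	3.8
171	Ile	Gly	R2R	4.24	0.7
171	Ile	Gln	RDR	4.51	-13.0
171	Ile	Gln	R2R	11.45	-7.8
171	Ile	Glu	RDR	5.20	-10.4
171	Ile	Glu	R2R	13.13	-8.6
171	Ile	HisA	RDR	2.29	5.4
171	Ile	HisA	R2R	10.22	2.5
171	Ile	HisB	RDR	2.27	3.0
171	Ile	HisB	R2R	10.28	2.7
171	Ile	Ile	RDR	3.36	1.9
171	Ile	Ile	R2R	3.76	1.6
171	Ile	Leu	RDR	10.75	4.0
171	Ile	Leu	R2R	6.06	-1.2
171	Ile	Lys	RDR	1.29	-3.4
171	Ile	Lys	R2R	8.88	-2.2
171	Ile	Met	RDR	3.46	3.2
171	Ile	Met	R2R	11.04	0.8
171	Ile	Phe	RDR	0.42	7.9
171	Ile	Phe	R2R	3.93	3.7
171	Ile	Ser	RDR	53.00	-0.05
171	Ile	Ser	R2R	8.85	2.3
171	Ile	Thr	RDR	31.76	1.3
171	Ile	Thr	R2R	6.20	1.8
171	Ile	Trp	RDR	0.22	0.3
171	Ile	Trp	R2R	0.68	1.3
171	Ile	Tyr	RDR	0.32	10.2
171	Ile	Tyr	R2R	2.44	17.2
171	Ile	Val	RDR	10.02	-4.9
171	Ile	Val	R2R	5.58	1.5
171	Pro	Ala	RDR	67.34	13.8
171	Pro	Ala	R2R	41.12	28.6
171	Pro	Arg	RDR	0.33	-3.3
171	Pro	Arg	R2R	2.79	4.5
171	Pro	Asn	RDR	38.82	1.0
171	Pro	Asn	R2R	34.36	19.6
171	Pro	Asp	RDR	44.67	2.4
171	Pro	Asp	R2R	32.47	6.2
171	Pro	Cys	RDR	48.66	4.7
171	Pro	Cys	R2R	7.22	23.5
171	Pro	Gly	RDR	2.34	2.4
171	Pro	Gly	R2R	1.77	2.9
171	Pro	Gln	RDR	26.00	1.0
171	Pro	Gln	R2R	8.23	12.6
171	Pro	Glu	RDR	25.12	-2.9
171	Pro	Glu	R2R	12.90	2.9
171	Pro	HisA	RDR	6.08	-1.4
171	Pro	HisA	R2R	17.49	12.7
171	Pro	HisB	RDR	7.10	1.2
171	Pro	HisB	R2R	21.91	13.6
171	Pro	Ile	RDR	11.04	-7.6
171	Pro	Ile	R2R	3.36	11.6
171	Pro	Leu	RDR	25.86	-5.4
171	Pro	Leu	R2R	8.82	10.3
171	Pro	Lys	RDR	2.55	-6.9
171	Pro	Lys	R2R	12.12	10.8
171	Pro	Met	RDR	8.28	2.0
171	Pro	Met	R2R	19.70	12.4
171	Pro	Phe	RDR	1.18	-17.4
171	Pro	Phe	R2R	8.95	8.9
171	Pro	Ser	RDR	58.28	7.7
171	Pro	Ser	R2R	36.09	25.4
171	Pro	Thr	RDR	39.23	1.2
171	Pro	Thr	R2R	13.80	19.4
171	Pro	Trp	RDR	0.26	-26.5
171	Pro	Trp	R2R	4.64	6.0
171	Pro	Tyr	RDR	0.46	-14.8
171	Pro	Tyr	R2R	4.86	4.5
171	Pro	Val	RDR	34.84	-4.7
171	Pro	Val	R2R	6.79	17.0
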