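# Relative binding free energies (kJ/mol) of the 14 polar mutations from the
# linear-interaction-energy method and from the combined OSP + TPF route
# (histidine tautomers averaged), with the experimental screen outcome.
site	p1prime	mutation	lie	osp_tpf	found
105	Ile	Arg	1.4	-2.5	1
105	Ile	Asn	-12.3	-14.1	1
105	Ile	Asp	34.0	1.1	0
105	Ile	Cys	5.1	-13.8	1
105	Ile	Gln	-8.9	-5.5	1
105	Ile	Glu	0.0	0.0	1
105	Ile	His	-1.2	-15.6	1
105	Ile	Lys	-20.6	-11.4	0
105	Ile	Met	-0.9	-6.2	1
105	Ile	Phe	-6.9	1.5	0
105	Ile	Ser	-10.5	-22.2	1
105	Ile	Thr	-10.2	-11.9	1
105	Ile	Trp	-15.8	-79.5	1
105	Ile	Tyr	2.8	-9.4	1
105	Pro	Arg	-18.5	-14.7	0
105	Pro	Asn	-20.4	-16.7	0
105	Pro	Asp	-47.1	6.9	0
105	Pro	Cys	-11.8	-12.2	0
105	Pro	Gln	-30.9	11.8	0
105	Pro	Glu	0.0	0.0	0
105	Pro	His	-23.2	-2.4	0
105	Pro	Lys	-11.0	16.1	0
105	Pro	Met	-24.8	-12.3	1
105	Pro	Phe	-29.7	5.3	0
105	Pro	Ser	-22.9	12.9	0
105	Pro	Thr	-19.0	11.5	0
105	Pro	Trp	-30.5	-18.2	0
105	Pro	Tyr	-20.3	9.0	0
171	Ile	Arg	4.8	-4.1	1
171	Ile	Asn	-0.1	-0.8	0
171	Ile	Asp	4.2	-10.3	0
171	Ile	Cys	8.8	5.4	1
171	Ile	Gln	-0.2	-8.4	0
171	Ile	Glu	-0.3	-9.9	1
171	Ile	His	0.4	2.2	0
171	Ile	Lys	-4.1	-4.5	1
171	Ile	Met	1.6	0.8	0
171	Ile	Phe	-0.1	3.0	0
171	Ile	Ser	3.4	-3.7	1
171	Ile	Thr	-6.7	-6.6	0
171	Ile	Trp	-1.8	-1.2	1
171	Ile	Tyr	-0.2	16.8	0
171	Pro	Arg	-2.2	4.9	1
171	Pro	Asn	-4.4	-1.8	1
171	Pro	Asp	-0.5	-3.9	1
171	Pro	Cys	7.1	0.7	1
171	Pro	Gln	2.4	-2.1	1
171	Pro	Glu	-0.1	-8.2	1
171	Pro	His	3.8	3.2	0
171	Pro	Lys	-2.8	5.3	0
171	Pro	Met	-14.2	8.3	0
171	Pro	Phe	4.2	6.7	0
171	Pro	Ser	-2.1	6.3	0
171	Pro	Thr	4.6	0.2	0
171	Pro	Trp	0.8	3.8	0
171	Pro	Tyr	1.6	-0.3	0
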