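# Relative substrate-binding free energies (kJ/mol) of the mutations
# Glu105Xxx and Gly171Xxx against the unmutated protease, with the outcome of
# the experimental random saturation-mutagenesis screen (found = 1 when the
# mutation appeared among active variants).
site	p1prime	mutation	relative_dG	found
105	Ile	Ala	-19.9	1
105	Ile	Arg	-2.5	1
105	Ile	Asn	-14.1	1
105	Ile	Asp	1.1	0
105	Ile	Cys	-13.8	1
105	Ile	Gly	-1.8	1
105	Ile	Gln	-5.5	1
105	Ile	Glu	0.0	1
105	Ile	HisA	-14.7	1
105	Ile	HisB	-16.5	1
105	Ile	Ile	-9.7	1
105	Ile	Leu	-10.7	1
105	Ile	Lys	-11.4	0
105	Ile	Met	-6.2	1
105	Ile	Phe	1.5	0
105	Ile	Ser	-22.2	1
105	Ile	Thr	-11.9	1
105	Ile	Trp	-79.5	1
105	Ile	Tyr	-9.4	1
105	Ile	Val	-9.7	1
105	Pro	Ala	-1.2	1
105	Pro	Arg	-14.7	0
105	Pro	Asn	-16.7	0
105	Pro	Asp	6.9	0
105	Pro	Cys	-12.2	0
105	Pro	Gly	0.1	0
105	Pro	Gln	11.8	0
105	Pro	Glu	0.0	0
105	Pro	HisA	-1.1	0
105	Pro	HisB	-3.6	0
105	Pro	Ile	6.1	0
105	Pro	Leu	7.2	0
105	Pro	Lys	16.1	0
105	Pro	Met	-12.3	1
105	Pro	Phe	5.3	0
105	Pro	Ser	12.9	0
105	Pro	Thr	11.5	0
105	Pro	Trp	-18.2	0
105	Pro	Tyr	9.0	0
105	Pro	Val	0.0	1
171	Ile	Ala	-14.3	1
171	Ile	Arg	-4.1	1
171	Ile	Asn	-0.8	0
171	Ile	Asp	-10.3	0
171	Ile	Cys	5.4	1
171	Ile	Gly	0.0	0
171	Ile	Gln	-8.4	0
171	Ile	Glu	-9.9	1
171	Ile	HisA	0.9	0
171	Ile	HisB	3.4	0
171	Ile	Ile	0.9	0
171	Ile	Leu	0.3	0
171	Ile	Lys	-4.5	1
171	Ile	Met	0.8	0
171	Ile	Phe	3.0	0
171	Ile	Ser	-3.7	1
171	Ile	Thr	-6.6	0
171	Ile	Trp	-1.2	1
171	Ile	Tyr	16.8	0
171	Ile	Val	-8.7	1
171	Pro	Ala	11.5	1
171	Pro	Arg	4.9	1
171	Pro	Asn	-1.8	1
171	Pro	Asp	-3.9	1
171	Pro	Cys	0.7	1
171	Pro	Gly	0.0	0
171	Pro	Gln	-2.1	1
171	Pro	Glu	-8.2	1
171	Pro	HisA	-4.5	0
171	Pro	HisB	10.9	0
171	Pro	Ile	-10.0	0
171	Pro	Leu	-7.8	0
171	Pro	Lys	5.3	0
171	Pro	Met	8.3	0
171	Pro	Phe	6.7	0
171	Pro	Ser	6.3	0
171	Pro	Thr	0.2	0
171	Pro	Trp	3.8	0
171	Pro	Tyr	-0.3	0
171	Pro	Val	-7.1	1
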