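# Binding free energies relative to the reference state (kJ/mol): the OSP term
# in the reporting reference-state variant, the corrected TPF charging term
# (blank for apolar side chains), and, where the published downstream
# arithmetic requires it, an explicit binding value (binding_dG) used verbatim.
# Wild-type residues (Glu at 105, Gly at 171) appear in both variants so the
# thermodynamic cycle can close within either.
site	p1prime	mutation	variant	osp_dG	tpf_corrected	binding_dG
105	Ile	Ala	RDR	-16.2
105	Ile	Arg	R2R	-1.9	7.8
105	Ile	Asn	RDR	-5.1	-5.3
105	Ile	Asp	RDR	-4.2	8.9
105	Ile	Cys	R2R	-16.3	11.0
105	Ile	Gly	RDR	-1.8
105	Ile	Gln	R2R	6.6	-3.6
105	Ile	Glu	RDR	-6.0	9.7
105	Ile	Glu	R2R	-1.2	9.7
105	Ile	HisA	R2R	-8.8	2.6
105	Ile	HisB	R2R	-7.0	-1.0
105	Ile	Ile	R2R	-1.2
105	Ile	Leu	RDR	-7.0
105	Ile	Lys	R2R	0.3	-3.2
105	Ile	Met	R2R	2.4	-0.2
105	Ile	Phe	R2R	10.2	-0.3
105	Ile	Ser	R2R	-12.6	-1.1
105	Ile	Thr	R2R	-2.6	-0.9
105	Ile	Trp	RDR	-79.2	3.4
105	Ile	Tyr	RDR	-9.1	3.4
105	Ile	Val	R2R	-1.2
105	Pro	Ala	RDR	-9.9
105	Pro	Arg	R2R	-20.0	2.2
105	Pro	Asn	R2R	-11.8	-8.0
105	Pro	Asp	RDR	2.7	-4.5
105	Pro	Cys	R2R	0.6	-15.9
105	Pro	Gly	RDR	0.1
105	Pro	Gln	R2R	14.6	-5.8
105	Pro	Glu	RDR	7.7	-16.4
105	Pro	Glu	R2R	5.6	-16.4	-3.1
105	Pro	HisA	R2R	-5.1	0.9
105	Pro	HisB	R2R	-8.4	1.7
105	Pro	Ile	R2R	3.0
105	Pro	Leu	RDR	-1.4
105	Pro	Lys	R2R	-4.1	17.1
105	Pro	Met	R2R	-15.2	-0.1
105	Pro	Phe	R2R	-5.1	7.4
105	Pro	Ser	RDR	2.8	1.4
105	Pro	Thr	RDR	6.2	-3.4
105	Pro	Trp	R2R	-21.7	0.4
105	Pro	Tyr	R2R	12.0	-6.1
105	Pro	Val	R2R	-3.1
171	Ile	Ala	RDR	-10.6
171	Ile	Arg	R2R	-2.1	-1.4
171	Ile	Asn	RDR	4.0	-1.0
171	Ile	Asp	RDR	-12.9	6.4
171	Ile	Cys	R2R	2.3	3.8
171	Ile	Gly	RDR	3.8
171	Ile	Gly	R2R	0.7
171	Ile	Gln	R2R	-7.8	0.1
171	Ile	Glu	R2R	-8.6	-0.6
171	Ile	HisA	R2R	2.6	-0.9
171	Ile	HisB	R2R	2.7	1.5
171	Ile	Ile	R2R	1.6
171	Ile	Leu	RDR	4.0
171	Ile	Lys	R2R	-2.2	-1.6
171	Ile	Met	R2R	0.8	0.7
171	Ile	Phe	R2R	3.7	-0.1
171	Ile	Ser	RDR	-0.1	0.1
171	Ile	Thr	RDR	1.3	-4.1
171	Ile	Trp	R2R	1.3	-1.7
171	Ile	Tyr	R2R	17.2	0.2
171	Ile	Val	RDR	-4.9
171	Pro	Ala	RDR	13.8
171	Pro	Arg	R2R	4.1	3.8
171	Pro	Asn	RDR	1.0	-0.3
171	Pro	Asp	RDR	2.4	-3.9
171	Pro	Cys	RDR	4.7	-1.7
171	Pro	Gly	RDR	2.4
171	Pro	Gly	R2R	2.9
171	Pro	Gln	RDR	1.0	-0.8
171	Pro	Glu	RDR	-2.9	-2.9
171	Pro	HisA	RDR	-1.4	-0.1
171	Pro	HisB	R2R	13.6	-0.5
171	Pro	Ile	RDR	-7.6
171	Pro	Leu	RDR	-5.4
171	Pro	Lys	R2R	10.8	-2.5
171	Pro	Met	R2R	12.4	-1.2
171	Pro	Phe	R2R	8.9	0.8
171	Pro	Ser	RDR	7.7	1.0
171	Pro	Thr	RDR	1.2	1.4
171	Pro	Trp	R2R	6.0	0.7
171	Pro	Tyr	R2R	4.5	-1.9
171	Pro	Val	RDR	-4.7
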