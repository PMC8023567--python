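# Raw third-power-fitting charging free energies (kJ/mol) for the net-charged
# mutations, with the published artifact correction and corrected value for
# cross-checking; the pipeline recomputes the correction from its components.
site	p1prime	mutation	raw	cor	corrected
105	Ile	Arg	10.2	-2.4	7.9
105	Ile	Asp	-19.4	28.3	8.9
105	Ile	Glu	-19.3	29.0	9.7
105	Ile	Lys	4.4	-7.5	-3.2
105	Pro	Arg	9.3	-7.1	2.2
105	Pro	Asp	-23.4	18.9	-4.5
105	Pro	Glu	-42.0	25.6	-16.4
105	Pro	Lys	29.8	-12.7	17.1
171	Ile	Arg	-0.3	-1.1	-1.4
171	Ile	Asp	5.3	1.1	6.4
171	Ile	Glu	-0.8	0.2	-0.6
171	Ile	Lys	0.7	-2.3	-1.6
171	Pro	Arg	4.2	-0.41	3.8
171	Pro	Asp	-4.7	0.85	-3.9
171	Pro	Glu	-4.6	1.63	-2.9
171	Pro	Lys	-1.3	-1.21	-2.5
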