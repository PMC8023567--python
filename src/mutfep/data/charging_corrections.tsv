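# Charging-correction components (kJ/mol) for the four net-charged mutations
# per leg: pol_dir = dG_pol + dG_dir (continuum-electrostatics polarization and
# direct terms), dsm = dG_dsm (analytic periodicity/summation term).
# Two cells were reconciled against the rows' published per-leg sums, which are
# internally consistent with the published totals: 171/Pro Arg bound dsm
# (sign) and 171/Pro Asp bound dsm.
site	p1prime	mutation	leg	pol_dir	dsm
105	Ile	Arg	bound	3.3	-17.3
105	Ile	Arg	unbound	13.0	-24.6
105	Ile	Asp	bound	4.1	14.8
105	Ile	Asp	unbound	-26.7	17.3
105	Ile	Glu	bound	11.9	14.3
105	Ile	Glu	unbound	-19.4	16.6
105	Ile	Lys	bound	7.0	-17.1
105	Ile	Lys	unbound	15.6	-18.2
105	Pro	Arg	bound	-1.2	-18.6
105	Pro	Arg	unbound	9.9	-22.7
105	Pro	Asp	bound	4.9	16.5
105	Pro	Asp	unbound	-14.2	16.7
105	Pro	Glu	bound	4.5	14.0
105	Pro	Glu	unbound	-23.7	16.6
105	Pro	Lys	bound	1.4	-18.6
105	Pro	Lys	unbound	15.2	-19.7
171	Ile	Arg	bound	-7.5	-53.7
171	Ile	Arg	unbound	-5.5	-54.6
171	Ile	Asp	bound	6.8	57.5
171	Ile	Asp	unbound	6.2	57.0
171	Ile	Glu	bound	5.2	58.0
171	Ile	Glu	unbound	6.1	56.8
171	Ile	Lys	bound	-6.7	-52.4
171	Ile	Lys	unbound	-4.9	-51.9
171	Pro	Arg	bound	-7.7	-52.5
171	Pro	Arg	unbound	-5.6	-54.2
171	Pro	Asp	bound	5.2	58.7
171	Pro	Asp	unbound	5.6	57.4
171	Pro	Glu	bound	6.2	56.9
171	Pro	Glu	unbound	3.5	58.0
171	Pro	Lys	bound	-3.9	-54.4
171	Pro	Lys	unbound	-1.0	-56.0
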