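# Published cross-table proportions (%) of simulation classification
# (favorable/unfavorable) against the experimental screen (found/not found),
# pooled over both mutation sites, per P1' residue and combined.
# tp = favorable & found, fp = favorable & not found,
# fn = unfavorable & found, tn = unfavorable & not found.
subset	tp	fp	fn	tn
Ile	61.1	13.8	2.8	22.2
Pro	22.2	22.2	8.3	47.3
all	41.7	18.1	5.6	34.7
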