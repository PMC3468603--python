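# synthetic gene annotation for tests and worked examples (0-based half-open);
# coordinates are plausible GRCh37-scale placements, not an annotation release
chr1	78300000	78500000	FUBP1_like
chr7	55000000	55300000	EGFR_like
chr9	21950000	22100000	CDKN2A_like
chr9	44650000	44800000	chr9cen_prox_locus
chr17	7500000	7600000	TP53_like
chr19	32400000	32700000	chr19q_recurrent_locus
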