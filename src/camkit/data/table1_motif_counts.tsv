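motif_class	zf_n	ch_n	consensus_n	primer_sets_n
AT/TA	3586	2700	16	4
CA/GT	2329	2711	22	16
GA/CT	543	1169	4	4
GC/CG	0	1	0	0
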