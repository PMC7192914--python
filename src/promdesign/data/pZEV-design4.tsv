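# name: pZEV-design4
# flank_5: CTAGCCCTGGATAGTAATCACGTGGTAGCGTTGGGGCAGTCGGCCAAACTATTTCCAGAGTTGGCAACTC
# flank_3: GTAGGGGCTTTGATCCACGTTTGCGCGGGCGGCCAGACGACAAAATGTGTTTCCCGTTCACTGAAGTGGT
kind	label	sequence	length	freq_A	freq_C	freq_G	freq_T
randomized	key35	.	35	0.25	0.25	0.25	0.25
randomized	spacer5p	.	13	0.25	0.25	0.25	0.25
constant	ZEV_1	GCGTGGGCG	.	.	.	.	.
randomized	internal1	.	37	0.25	0.25	0.25	0.25
constant	ZEV_2	GCGTGGGCG	.	.	.	.	.
randomized	internal2	.	37	0.25	0.25	0.25	0.25
constant	ZEV_3	GCGTGGGCG	.	.	.	.	.
randomized	spacer_tata	.	20	0.25	0.25	0.25	0.25
constant	TATA18	GTATATAAAGTATATAAA	.	.	.	.	.
randomized	core	.	30	0.3	0.12	0.12	0.46
constant	TSS	ACATCAA	.	.	.	.	.
randomized	utr	.	22	0.35	0.25	0	0.4
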