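# name: pGPD-final
# flank_5: TAATATCGAATCGGGGTATACTCTATACGAACAAGCCTCAAATACGGCACGATTCTCTTCACGCCCCGCC
# flank_3: GACAACATCTCTTAACAGTTAACGCGCTGAAGCAAGCTAAGTCAAGCCATTGTTAGAATGTTCGACAGAA
kind	label	sequence	length	freq_A	freq_C	freq_G	freq_T
randomized	key35	.	35	0.25	0.25	0.25	0.25
randomized	spacer_up	.	30	0.25	0.25	0.25	0.25
constant	RAP1_1	CACCCATACA	.	.	.	.	.
randomized	spacer1	.	20	0.25	0.25	0.25	0.25
constant	RAP1_2	CACCCATACA	.	.	.	.	.
randomized	spacer2	.	20	0.25	0.25	0.25	0.25
constant	GCR1_1	CTTCC	.	.	.	.	.
randomized	spacer3	.	20	0.25	0.25	0.25	0.25
constant	GCR1_2	CTTCC	.	.	.	.	.
randomized	spacer_tata	.	50	0.25	0.25	0.25	0.25
constant	TATA	TATATAAA	.	.	.	.	.
randomized	core	.	54	0.3	0.12	0.12	0.46
constant	TSS	ACATCA	.	.	.	.	.
randomized	utr	.	30	0.35	0.25	0	0.4
constant	utr_end	AAAACAAAA	.	.	.	.	.
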