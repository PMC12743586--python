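peptide	protein_id	gene_symbol	freq_mean	freq_sd	1h	3h	6h	12h	24h
SAPFSSDSEQGNA	A1M	Ambp	100.0	0.0	unchanged	unchanged	up	up	up
AYLTSASSRPT	A1M	Ambp	73.79	7.69	unchanged	up	up	up	unchanged
APFSSDSEQGNA	A1M	Ambp	66.79	5.16	unchanged	unchanged	up	up	unchanged
SSQDPLVVQEGSR	IC1	Serping1	73.64	9.18	unchanged	unchanged	unchanged	up	unchanged
AAPAPAPAPAPAPAKPKEE	MYL1	Myl1	71.93	16.61	unchanged	unchanged	unchanged	up	up
RKEEPPSLRPAPPPISGGGY	FIBB	Fgb	68.64	16.91	up	unchanged	unchanged	unchanged	unchanged
VAPEEHPTLLTEAPLNPK	ACTS	Acta1	59.29	1.43	unchanged	unchanged	unchanged	up	up
VAPEEHPVLLTEAPLNPK	ACTG	Actg1	58.07	20.5	unchanged	unchanged	unchanged	down	down
VNPDDVGGEALG	HBB1	Hbb	52.57	7.38	unchanged	unchanged	unchanged	up	unchanged
DDPSVHSQPVTPLQLFEGRRS	CO4	C4a	47.43	17.45	unchanged	unchanged	down	unchanged	unchanged
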