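# Built-in signature motifs of the bacterial Delta-4,5-hexuronate-2-O-sulfatase
# family (SulfAtlas S1_9), anchored on PB2SF protein coordinates.
# Columns: motif, ref_pos, kind, allowed (. = none), weight (conservation
# fraction; 0 for wildcard/optional), note.
#
# Position 92 (the Cys/Ser formylglycine precursor of the universal
# arylsulfatase core C/S-X-P-X-R) is published with a two-residue allowed set
# and no conservation percentage; it is encoded with weight 1.00 because C or
# S is universal at that position across the S1 family.
#
# The published motif-E indices contain a typographical jump: the glutamate
# between G440 and X442 is printed as E444 although N444 follows three
# positions later.  It is encoded here at 441 (the only index consistent with
# strictly increasing positions) and flagged in the note column rather than
# silently renumbered.
A	44	fixed	P	0.70
A	45	fixed	N	0.99
A	46	fixed	I	0.74
A	47	fixed	L	0.57
A	48	wildcard	.	0
A	49	fixed	I	0.95
A	50	wildcard	.	0
A	51	fixed	T	0.63
A	52	fixed	D	1.00	catalytic
B	86	fixed	Y	1.00
B	87	fixed	C	0.64
B	88	wildcard	.	0
B	89	wildcard	.	0
B	90	fixed	P	1.00
B	91	fixed	L	0.82
B	92	fixed	CS	1.00	fgly_precursor
B	93	wildcard	.	0
B	94	fixed	P	1.00	core_motif
B	95	fixed	S	0.86
B	96	fixed	R	1.00	core_motif
B	97	wildcard	.	0
B	98	fixed	S	0.50
B	99	wildcard	.	0
B	100	wildcard	.	0
B	101	fixed	T	0.76
B	102	fixed	G	0.97
C	194	fixed	P	1.00
C	195	fixed	F	0.95
C	196	wildcard	.	0
C	197	fixed	L	0.68
C	198	fixed	V	0.52
C	199	fixed	A	0.54
C	200	wildcard	.	0
C	201	fixed	F	0.73
C	202	wildcard	.	0
C	203	fixed	N	0.97
C	204	fixed	P	1.00
C	205	fixed	H	1.00	catalytic
C	206	fixed	N	0.68
C	207	fixed	I	0.95
C	208	fixed	C	0.91
D	301	fixed	N	0.78
D	302	fixed	T	0.98
D	303	wildcard	.	0
D	304	fixed	V	0.65
D	305	fixed	I	0.54
D	306	fixed	F	0.82
D	307	wildcard	.	0
D	308	fixed	S	0.70
D	309	fixed	D	0.99
D	310	fixed	H	1.00	catalytic
D	311	fixed	G	1.00
D	312	fixed	D	0.86
D	313	fixed	G	0.75
D	314	wildcard	.	0
D	315	fixed	G	0.58
E	417	fixed	Y	0.67
E	418	fixed	K	1.00
E	419	fixed	Y	1.00
E	420	wildcard	.	0
E	421	optional	.	0
E	422	wildcard	.	0
E	423	fixed	Y	0.86
E	424	wildcard	.	0
E	425	wildcard	.	0
E	426	fixed	G	0.84
E	427	optional	.	0
E	428	optional	.	0
E	429	wildcard	.	0
E	430	fixed	E	1.00
E	431	fixed	Q	0.48
E	432	fixed	L	0.99
E	433	fixed	F	0.47
E	434	fixed	D	0.87
E	435	fixed	M	0.50
E	436	wildcard	.	0
E	437	wildcard	.	0
E	438	fixed	D	1.00
E	439	fixed	P	0.52
E	440	fixed	G	0.92
E	441	fixed	E	1.00	printed_as_E444
E	442	wildcard	.	0
E	443	wildcard	.	0
E	444	fixed	N	0.92
E	445	fixed	L	0.95
E	446	fixed	A	0.80
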