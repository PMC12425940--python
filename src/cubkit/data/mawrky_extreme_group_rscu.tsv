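amino_acid	codon	rscu_high	rscu_low
L	UUA	0.37	0.4
L	UUG	0.48	1.63
L	CUU	0.73	0.69
L	CUC	2.13	1.1
L	CUA	0.37	0.53
L	CUG	1.92	1.66
V	GUU	0.56	0.69
V	GUC	1	1.24
V	GUA	0.29	0.47
V	GUG	2.16	1.59
S	UCU	0.67	0.89
S	UCC	1.43	0.64
S	UCA	0.37	0.95
S	AGU	0.27	0.4
S	AGC	2.12	1.9
S	UCG	1.14	1.22
P	CCU	1.07	1.36
P	CCC	1.02	0.7
P	CCA	0.6	1.34
P	CCG	1.31	0.6
T	ACU	0.74	0.81
T	ACC	1.69	0.51
T	ACA	0.43	1.53
T	ACG	1.14	1.15
A	GCU	1.05	1.12
A	GCC	0.99	0.62
A	GCA	1	0.89
A	GCG	0.96	1.38
Y	UAU	0.48	0.73
Y	UAC	1.52	1.27
H	CAU	0.77	1.27
H	CAC	1.23	0.73
Q	CAA	0.69	1.21
Q	CAG	1.31	0.79
N	AAU	0.4	0.99
N	AAC	1.6	1.02
K	AAA	0.49	0.5
K	AAG	1.51	1.5
D	GAU	0.79	1.23
D	GAC	1.21	0.77
E	GAA	0.4	0.78
E	GAG	1.6	1.22
C	UGU	0.41	0.61
C	UGC	1.44	1.39
F	UUU	0.31	0.68
F	UUC	1.69	1.32
R	CGU	0.71	0.12
R	CGC	1.29	0.3
R	CGA	0.49	0.41
R	CGG	1.11	0.68
R	AGA	1.23	2.12
R	AGG	1.19	2.36
G	GGU	0.72	0.38
G	GGC	2.05	1.63
G	GGA	0.75	1.08
G	GGG	0.63	0.9
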