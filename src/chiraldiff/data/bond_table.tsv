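# Reference covalent bond lengths (angstrom) with acceptance margins,
# per unordered element pair and bond order. Values are standard published
# covalent bond lengths for H/C/N/O/F; margins are order-dependent
# (single 0.10, double 0.05, triple 0.03), the lookup convention used by
# distance-based bond inference in equivariant molecule generation.
# columns: element1 element2 order length_A margin_A
H	H	1	0.74	0.10
H	C	1	1.09	0.10
H	N	1	1.01	0.10
H	O	1	0.96	0.10
H	F	1	0.92	0.10
C	C	1	1.54	0.10
C	N	1	1.47	0.10
C	O	1	1.43	0.10
C	F	1	1.35	0.10
N	N	1	1.45	0.10
N	O	1	1.40	0.10
N	F	1	1.36	0.10
O	O	1	1.48	0.10
O	F	1	1.42	0.10
F	F	1	1.41	0.10
C	C	2	1.34	0.05
C	N	2	1.29	0.05
C	O	2	1.20	0.05
N	N	2	1.25	0.05
N	O	2	1.21	0.05
O	O	2	1.21	0.05
C	C	3	1.20	0.03
C	N	3	1.16	0.03
N	N	3	1.10	0.03
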