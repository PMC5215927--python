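# 9aaTAD family members, transcribed in printed order.
# VP16 and EBNA2 each appear twice in the printed list; duplicates are
# retained here and collapsed at load time.
# Columns: printed_order, name
printed_order	name
1	Gal4
2	Oaf1
3	Pip2
4	Pdr1
5	Pdr3
6	Leu3
7	Tea1
8	Pho4
9	Gln3
10	Gcn4
11	Msn2
12	Msn4
13	Rtg3
14	E2A
15	MLL
16	p53-TAD-I
17	p53-TAD-II
18	HNF4 / NHR-49
19	FOXO3
20	NF-kB
21	NFAT
22	CEBPA/E
23	ESX
24	ELF3
25	ETV1
26	KLF2/4
27	EBNA2
28	VP16
29	HSF1
30	HSF2
31	HsfA
32	Gli3
33	Sox18
34	PIF
35	Dreb2a
36	MTF1
37	OREB1
38	WRKY45
39	NS1
40	MKL1
41	TRP32
42	VP16
43	EBNA2
44	KBP220
45	ECapLL
46	P201
47	AH
48	B42
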