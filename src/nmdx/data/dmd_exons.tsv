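# Coding-sequence length (nt) of each of the 79 exons of the full-length muscle
# dystrophin transcript (Dp427m, NM_004006.2). Exon 1 and exon 79 lengths are the
# coding portions only (both exons also carry UTR). Total = 11058 nt = 3685 codons
# + stop, the length of the dystrophin open reading frame.
exon	coding_length
1	31
2	62
3	93
4	78
5	93
6	173
7	119
8	182
9	129
10	189
11	182
12	151
13	120
14	105
15	105
16	180
17	176
18	124
19	88
20	242
21	181
22	146
23	213
24	114
25	156
26	171
27	183
28	136
29	149
30	162
31	111
32	174
33	156
34	171
35	180
36	129
37	171
38	123
39	138
40	153
41	183
42	195
43	173
44	148
45	176
46	148
47	150
48	186
49	102
50	109
51	233
52	118
53	212
54	155
55	190
56	173
57	157
58	121
59	269
60	148
61	201
62	75
63	62
64	75
65	202
66	107
67	167
68	112
69	137
70	106
71	39
72	66
73	66
74	159
75	147
76	120
77	72
78	32
79	28
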