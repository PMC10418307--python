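94	80	69	18
79	69	59	93
47	50	55	14
52	47	64	20
146	115	66	71
65	49	47	42
48	33	42	88
76	41	20	60
47	47	33	19
64	32	58	20
97	71	57	60
50	43	86	37
39	29	63	53
59	75	54	42
40	47	85	32
52	57	72	33
49	58	26	78
23	53	36	115
50	31	40	42
53	68	28	41
37	44	51	68
95	25	66	53
44	85	38	13
58	50	40	59
67	84	29	45
34	55	43	26
60	31	134	44
71	44	73	38
81	110	29	22
47	40	58	25
69	25	36	66
105	49	68	33
28	49	33	50
114	90	97	47
45	70	62	37
35	38	83	38
68	73	25	57
57	40	55	57
92	34	37	27
60	37	41	45
60	43	32	29
55	48	46	99
74	57	108	46
57	57	40	17
22	56	39	47
46	38	63	37
65	19	45	50
40	92	28	53
26	57	41	95
89	59	86	39
70	18	64	122
20	60	40	16
47	33	21	35
88	44	47	60
35	21	50	39
46	78	47	32
68	96	81	32
65	43	129	104
41	34	9	66
56	36	61	74
41	26	10	34
55	37	50	71
31	50	51	35
15	31	40	33
63	64	31	51
29	92	39	33
74	25	56	29
43	46	35	34
47	102	72	36
70	28	30	39
40	54	50	62
55	33	17	10
47	25	53	41
55	24	45	128
78	60	57	51
41	36	59	21
52	84	53	20
37	22	73	27
23	75	69	58
39	53	43	80
23	45	99	50
75	117	45	34
64	59	26	18
67	44	50	20
31	24	35	25
31	48	34	80
34	25	37	51
87	88	66	62
72	74	40	62
40	76	63	34
72	56	89	68
27	95	79	60
21	62	8	26
63	17	52	19
23	25	23	35
19	68	27	26
21	30	83	121
36	31	60	37
87	48	21	22
32	31	50	42
12	40	86	75
75	64	59	44
23	50	80	38
24	35	77	135
26	49	28	38
77	42	32	12
50	67	48	11
57	60	65	64
54	51	55	45
35	43	43	36
44	51	51	74
73	68	61	69
93	49	56	49
49	68	79	26
57	28	51	50
69	81	90	16
42	37	30	33
31	23	237	18
74	29	16	63
53	67	63	52
50	92	23	33
65	78	18	49
68	30	44	46
39	51	39	48
19	40	31	51
91	46	32	66
112	38	49	43
62	48	24	12
67	42	42	65
106	33	47	73
57	33	27	50
67	94	52	100
37	21	17	64
46	25	103	22
49	91	29	22
24	55	12	61
62	37	23	33
88	28	46	35
52	14	40	27
28	58	55	37
61	66	37	57
31	42	29	67
32	25	59	42
110	38	68	98
41	30	81	41
75	29	80	54
53	105	156	52
35	26	32	103
55	24	99	61
115	69	51	40
92	38	49	18
96	22	52	47
57	47	48	15
58	86	51	63
52	36	39	90
29	52	30	36
31	19	88	53
57	57	51	64
26	35	44	63
42	46	74	16
29	50	23	56
67	60	39	78
84	68	39	40
17	40	36	90
59	25	65	55
51	88	56	34
20	44	42	10
28	22	45	28
46	64	95	15
30	30	21	44
22	21	47	51
76	45	43	81
47	28	46	88
27	38	29	46
24	45	63	90
18	90	26	42
46	52	77	41
75	40	100	59
55	45	32	53
48	27	64	104
51	69	38	47
53	23	19	15
82	60	47	84
22	21	35	61
42	59	70	24
63	29	77	56
23	41	21	33
33	35	89	115
42	40	10	49
53	63	99	27
50	31	64	42
82	50	34	42
31	28	87	59
37	68	53	29
76	61	40	25
18	48	55	40
50	89	36	78
42	49	71	53
17	65	45	29
62	36	46	41
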