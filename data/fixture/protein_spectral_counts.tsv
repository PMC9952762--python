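feature_id	WT_1	WT_2	WT_3	KO_1	KO_2	KO_3
G0000	18	10	11	20	18	22
G0003	14	21	15	18	8	25
G0004	89	103	100	439	457	452
G0006	27	37	31	37	32	38
G0007	20	24	16	26	26	21
G0008	11	13	15	2	5	6
G0017	17	19	22	17	20	18
G0018	14	11	17	9	16	16
G0019	0	9	6	5	5	8
G0020	38	33	34	56	38	36
G0022	24	32	35	23	24	31
G0024	32	39	40	35	30	30
G0025	33	35	19	25	27	24
G0026	20	26	19	27	16	15
G0029	6	12	5	0	3	4
G0035	13	21	24	26	20	23
G0036	5	11	18	16	10	17
G0042	86	67	76	97	92	117
G0043	131	113	126	133	144	143
G0044	4	6	0	5	8	4
G0045	27	20	20	28	22	22
G0046	11	15	21	87	86	82
G0053	21	17	25	25	17	13
G0054	94	100	98	117	112	111
G0055	44	54	45	5	7	5
G0056	3	2	5	2	2	0
G0057	66	58	53	43	45	39
G0058	13	10	9	53	58	65
G0062	26	31	32	27	24	27
G0063	11	6	15	11	7	13
G0068	6	5	12	13	10	7
G0069	8	8	12	10	6	10
G0070	27	22	24	32	27	26
G0073	99	97	96	96	103	119
G0075	15	16	16	7	6	13
G0076	7	10	19	10	10	10
G0079	7	7	5	5	4	4
G0085	10	12	14	74	77	77
G0088	20	20	22	13	12	21
G0090	11	11	12	15	13	12
G0092	36	34	33	138	164	159
G0097	14	16	17	16	10	15
G0100	16	14	27	24	14	11
G0101	89	87	93	106	98	82
G0105	200	190	223	57	65	59
G0106	214	200	197	231	245	225
G0107	13	5	12	16	20	17
G0113	13	16	17	15	24	17
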