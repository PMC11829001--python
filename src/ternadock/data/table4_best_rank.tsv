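pdb_id	botcp_rank	botcp_clusters	botcp_near_native	pipeline_rank	pipeline_clusters	pipeline_near_native
5T35-DA	76	765	94.1	7	59	71.818
5T35-HE	51	763	88.9	13	66	37.500
6BN7-BC	89	917	6.7	2	70	74.282
6BOY-BC	19	720	80	4	93	97.143
6HAX-BA	8	816	100	8	85	82.051
6HAX-FE	14	795	100	3	107	32.099
6HAY-BA	2	914	100	36	94	100
6HAY-FE	5	946	100	60	85	14.286
6HR2-BA	73	727	41.7	6	90	12.121
6HR2-FE	69	679	25	35	90	26.667
6SIS-DA	71	339	100	4	72	53.333
6SIS-HE	8	365	100	17	60	55.844
6W7O-CA	12	269	9.4	62	92	100
6W7O-DB	4	271	29.2	58	62	100
6W8I-DA	13	362	96.6	11	82	66.667
6W8I-EB	6	364	25	32	60	16.667
6W8I-FC	35	365	84.6	1	65	52.381
6ZHC-AD	7	670	75	29	54	90.909
7JTO-LB	15	403	50	27	75	31.818
7JTP-LA	42	170	88.1	4	97	74.257
7KHH-CD	9	NA	NA	12	65	65.274
7Q2J-CD	82	322	79.1	14	93	11.429
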