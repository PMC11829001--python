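pdb_id	botcp_rank	botcp_clusters	botcp_near_native	pipeline_rank	pipeline_clusters	pipeline_near_native
5T35-DA	5	370	0.84	2	59	54.198
5T35-HE	2	315	31.45	7	66	53.097
6BN7-BC	30	606	3.33	1	70	84.615
6BOY-BC	12	423	77.78	3	93	73.481
6HAX-BA	7	300	1.04	7	85	4.667
6HAX-FE	6	283	0.14	3	107	32.099
6HAY-BA	3	374	98.94	18	94	44.643
6HAY-FE	1	377	30.47	19	85	5.085
6HR2-BA	5	302	1.11	1	90	75
6HR2-FE	4	327	0.6	5	90	0.41
6SIS-DA	1	161	17.76	4	72	53.333
6SIS-HE	1	189	2.35	7	60	58.025
6W7O-CA	1	102	35.79	4	92	3.03
6W7O-DB	1	106	17.24	2	62	0.225
6W8I-DA	5	191	16.67	5	82	3.623
6W8I-EB	93	196	4	2	60	3
6W8I-FC	1	188	8.7	1	65	52.381
6ZHC-AD	8	194	5.9	14	54	1.538
7JTO-LB	4	199	4.49	1	75	0.149
7JTP-LA	2	49	0.43	1	97	49.4
7KHH-CD	3	160	0.44	1	65	4.02
7Q2J-CD	8	69	1.1	2	93	1.327
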