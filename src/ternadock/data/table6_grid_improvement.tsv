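pdb_id	seed_dockq	translated_dockq	rotated_dockq	improvement_pct
5T35-DA	0.546	0.486	0.778	42.491
5T35-HE	0.555	0.507	0.785	41.441
6BN7-BC	0.420	0.360	0.580	38.095
6BOY-BC	0.487	0.353	0.589	20.945
6HAX-BA	0.304	0.450	0.540	77.632
6HAX-FE	0.080	0.078	0.302	277.5
6HAY-BA	0.192	0.260	0.556	189.583
6HAY-FE	0.095	0.131	0.252	165.263
6HR2-BA	0.204	0.199	0.506	148.039
6HR2-FE	0.191	0.193	0.501	162.304
6SIS-DA	0.575	0.662	0.644	12
6SIS-HE	0.564	0.495	0.754	33.688
6W7O-CA	0.659	0.606	0.632	-4.097
6W7O-DB	0.082	0.206	0.441	437.805
6W8I-DA	0.161	0.149	0.700	334.783
6W8I-EB	0.181	0.270	0.489	170.166
6W8I-FC	0.079	0.065	0.602	662.025
6ZHC-AD	0.182	0.255	0.417	129.121
7JTO-LB	0.074	0.061	0.340	359.459
7JTP-LA	0.326	0.216	0.674	106.748
7KHH-CD	0.705	0.629	0.756	7.234
7Q2J-CD	0.116	0.157	0.360	210.345
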