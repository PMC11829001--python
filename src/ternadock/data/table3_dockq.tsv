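pdb_id	botcp_fnat	botcp_irmsd	botcp_lrmsd	botcp_dockq	botcp_class	pipeline_fnat	pipeline_irmsd	pipeline_lrmsd	pipeline_dockq	pipeline_class	max_dockq
5T35-DA	0.818	1.97	5.192	0.638	M	1	1.361	4.46	0.778	M	0.85
5T35-HE	0.265	2.029	8.617	0.37	A	1	1.392	4	0.785	M	0.88
6BN7-BC	0.286	3.101	7.441	0.347	A	1	3.543	7.102	0.58	M	0.8
6BOY-BC	0.568	2.59	10.111	0.411	A	0.9	2.926	6.111	0.589	M	0.81
6HAX-BA	0.684	2.436	5.348	0.558	M	1	2.486	11.479	0.54	M	0.85
6HAX-FE	0.444	1.444	8.772	0.483	A	0.667	6.787	17.335	0.302	A	0.85
6HAY-BA	0.786	0.972	2.977	0.794	M	1	4.216	7.585	0.556	M	0.89
6HAY-FE	0.8	1.866	3.033	0.693	M	0.333	4.234	12.669	0.252	A	0.87
6HR2-BA	0.45	2.731	14.466	0.313	A	1	4.317	10.194	0.506	M	0.81
6HR2-FE	0.625	2.728	14.449	0.371	A	1	4.393	10.415	0.501	M	0.84
6SIS-DA	0.7	1.701	5.031	0.626	M	0.8	1.403	6.97	0.644	M	0.86
6SIS-HE	0.458	2.365	4.76	0.502	M	1	1.509	4.727	0.754	M	0.83
6W7O-CA	0.333	3.278	6.647	0.376	A	1	2.957	5.682	0.632	M	0.84
6W7O-DB	0.476	2.585	7.988	0.42	A	0.818	3.626	11.341	0.441	A	0.83
6W8I-DA	0.188	2.393	4.402	0.419	A	1	1.894	5.359	0.7	M	0.84
6W8I-EB	0.565	1.484	3.649	0.638	M	0.625	2.281	7.857	0.489	A	0.79
6W8I-FC	1	5.882	8.805	0.38	A	1	1.931	9.789	0.602	M	0.86
6ZHC-AD	0.053	3.42	5.545	0.305	A	1	3.766	23.586	0.417	A	0.91
7JTO-LB	0.5	3.051	4.82	0.31	A	0.286	2.287	9.741	0.34	A	0.76
7JTP-LA	0.7	2.694	7.715	0.495	A	1	1.856	6.57	0.674	M	0.84
7KHH-CD	0.333	3.771	15.829	0.231	A	0.8	1.284	2.974	0.756	M	0.92
7Q2J-CD	0.385	1.463	3.165	0.592	M	0.5	3.694	9.617	0.36	A	0.88
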