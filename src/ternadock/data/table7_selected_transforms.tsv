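pdb_id	tx	ty	tz	rx	ry	rz
5T35-DA	-3	3	-4.5	-15	-10	-5
5T35-HE	-3	3	-4.5	-15	-10	-5
6BN7-BC	-4.5	0	-3	-15	5	15
6BOY-BC	-3	0	-4.5	-10	-10	15
6HAX-BA	-1.5	-3	1.5	-5	-15	0
6HAX-FE	-3	1.5	0	-5	-5	15
6HAY-BA	-4.5	1.5	4.5	15	15	-10
6HAY-FE	-4.5	0	-4.5	-5	-10	10
6HR2-BA	-4.5	1.5	0	-15	-10	-10
6HR2-FE	-4.5	1.5	0	-15	-10	-10
6SIS-DA	-1.5	-1.5	1.5	-5	-5	0
6SIS-HE	-3	3	-4.5	-15	-10	-5
6W7O-CA	1.5	-1.5	4.5	5	5	0
6W7O-DB	4.5	-4.5	-3	15	-15	15
6W8I-DA	3	1.5	1.5	-15	-15	15
6W8I-EB	3	1.5	0	-15	-5	5
6W8I-FC	0	-1.5	1.5	-15	-15	-15
6ZHC-AD	0	-1.5	-1.5	-10	-15	-15
7JTO-LB	-1.5	-1.5	3	-10	15	-15
7JTP-LA	-4.5	3	4.5	-5	-5	-15
7KHH-CD	1.5	-3	0	10	-5	15
7Q2J-CD	-3	3	4.5	-15	0	0
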