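mother	offspring	tissue_pattern	n_consistent_regions	n_diff_homoplasmic	n_diff_php	n_diff_lhp	note
Family1-M	Family1-C	B-B	38	0	0	0
Family2-M	Family2-C	B-B	38	0	0	0
Family3-M	Family3-C	B-B	36	0	1	1
Family4-M	Family4-C	B-B	37	0	0	1
Family5-M	Family5-C	B-B	38	0	0	0
Family6-M	Family6-C	B-B	38	0	0	0
Family7-M	Family7-C	B-B	38	0	0	0
Family8-M	Family8-C	B-B	38	0	0	0
JX-N	JX-M1	B-B	38	0	0	0
JX-N	JX-M2	B-B	37	0	0	1
JX-M1	JX-C1	B-B	38	0	0	0
JX-M1	JX-C2	B-B	38	0	0	0
JX-M2	JX-C3	B-B	37	0	0	1	published row prints 0 differences with no details; encoded as one 302-315 length unit
P01-B	P03-B	B-B	36	0	1	1
P01-B	P04-B	B-B	38	0	0	0
P01-B	P06-B	B-B	37	0	0	1
P01-B	P08-B	B-B	36	0	1	1
P01-B	P09-B	B-B	36	0	0	2
P03-B	P12-B	B-B	35	0	3	1
P04-B	P13-B	B-B	37	0	0	1
P06-B	P14-B	B-B	37	0	1	0
P08-B	P15-B	B-B	37	0	1	0
P12-B	P18-B	B-B	35	0	3	0
P01-B	P03-H	B-H	36	0	0	2
P01-B	P04-H	B-H	37	0	0	1
P01-B	P06-H	B-H	36	1	0	1
P01-B	P08-H	B-H	35	0	3	1
P01-B	P09-H	B-H	35	0	1	2
P03-B	P12-H	B-H	36	0	1	1
P04-B	P13-H	B-H	35	0	1	2
P06-B	P14-H	B-H	36	0	1	2
P08-B	P15-H	B-H	35	0	2	1	published row prints 36 consistent regions, inconsistent with its own 2/1 counts over ATP6, TV and RNR1
P12-B	P18-H	B-H	36	0	2	0
P01-H	P03-H	H-H	35	0	2	2
P01-H	P04-H	H-H	36	0	2	1
P01-H	P06-H	H-H	35	1	2	1
P01-H	P08-H	H-H	33	0	5	2
P01-H	P09-H	H-H	34	0	3	2
P03-H	P12-H	H-H	36	0	0	2
P04-H	P13-H	H-H	36	0	1	1
P06-H	P14-H	H-H	35	1	1	1
P08-H	P15-H	H-H	34	0	4	1
P12-H	P18-H	H-H	36	0	2	0
P01-H	P03-B	H-B	34	0	3	2
P01-H	P04-B	H-B	35	0	2	2
P01-H	P06-B	H-B	35	0	2	2	published row prints 34 consistent regions, inconsistent with its listed distinct regions CR, ND4 and RNR1
P01-H	P08-B	H-B	34	0	3	2
P01-H	P09-B	H-B	35	0	2	2
P03-H	P12-B	H-B	34	0	2	2
P04-H	P13-B	H-B	38	0	0	0
P06-H	P14-B	H-B	35	1	1	1
P08-H	P15-B	H-B	34	0	5	0
P12-H	P18-B	H-B	37	0	1	0
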