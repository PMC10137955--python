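pedigree_id	individual_id	mother_id	sex
P	P01		F
P	P03	P01	F
P	P04	P01	F
P	P06	P01	F
P	P08	P01	F
P	P09	P01	M
P	P12	P03	F
P	P13	P04	F
P	P14	P06	M
P	P15	P08	M
P	P18	P12	M
JX	JX-N		F
JX	JX-M1	JX-N	F
JX	JX-M2	JX-N	F
JX	JX-C1	JX-M1	U
JX	JX-C2	JX-M1	U
JX	JX-C3	JX-M2	U
Family1	Family1-M		F
Family1	Family1-C	Family1-M	U
Family2	Family2-M		F
Family2	Family2-C	Family2-M	U
Family3	Family3-M		F
Family3	Family3-C	Family3-M	U
Family4	Family4-M		F
Family4	Family4-C	Family4-M	U
Family5	Family5-M		F
Family5	Family5-C	Family5-M	U
Family6	Family6-M		F
Family6	Family6-C	Family6-M	U
Family7	Family7-M		F
Family7	Family7-C	Family7-M	U
Family8	Family8-M		F
Family8	Family8-C	Family8-M	U
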